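"""Published reference results for the two wheat benchmark data sets.

The 13-model roster has been benchmarked on two CIMMYT wheat disease-count
data sets (the same shapes :func:`countgs.simulate.make_benchmark_dataset`
emulates).  This module carries the per-trait test metrics of those
benchmark runs as data — one row per (model, interaction, trait) with MSE,
MAAPE and APC and their bootstrap standard errors — together with the
summary arithmetic used to report them: across-trait averages and the
percent by which the best model beat the worst.

Only per-trait rows are stored; every 'Average' value and every percent
superiority is recomputed here from them.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .evaluation import average_across_traits, percent_superiority

# columns: model, interaction (WI = without, I = with G x E columns), trait,
# mse, se_mse, maape, se_maape, apc, se_apc
_DATASET1 = """\
model,interaction,trait,mse,se_mse,maape,se_maape,apc,se_apc
UPDN_1,WI,y1,49.792,7.579,0.596,0.024,0.546,0.054
UPDN_1,WI,y2,51.319,7.742,0.662,0.015,0.523,0.06
UPDN_2,WI,y1,46.03,4.51,0.607,0.023,0.55,0.043
UPDN_2,WI,y2,46.611,7.902,0.668,0.024,0.535,0.067
UPDN_3,WI,y1,46.08,4.969,0.623,0.021,0.553,0.048
UPDN_3,WI,y2,48.441,6.686,0.681,0.021,0.524,0.061
UPDN_4,WI,y1,44.609,5.645,0.625,0.018,0.554,0.032
UPDN_4,WI,y2,49.637,7.102,0.673,0.015,0.523,0.078
MPDN_1,WI,y1,45.507,10.464,0.581,0.047,0.87,0.025
MPDN_1,WI,y2,37.971,9.21,0.583,0.048,0.865,0.026
MPDN_2,WI,y1,45.294,10.069,0.591,0.048,0.863,0.026
MPDN_2,WI,y2,36.453,9.294,0.582,0.049,0.86,0.027
MPDN_3,WI,y1,48.682,10.454,0.595,0.048,0.854,0.027
MPDN_3,WI,y2,39.857,8.977,0.612,0.047,0.853,0.028
MPDN_4,WI,y1,49.999,10.283,0.625,0.046,0.831,0.031
MPDN_4,WI,y2,41.182,8.96,0.614,0.048,0.834,0.031
GPR_0.5,WI,y1,39.964,8.811,0.583,0.047,0.889,0.022
GPR_0.5,WI,y2,36.945,9.926,0.592,0.048,0.861,0.025
GPR_0.25,WI,y1,36.732,7.982,0.577,0.047,0.896,0.021
GPR_0.25,WI,y2,35.138,9.154,0.592,0.049,0.867,0.025
GPR_0.75,WI,y1,41.012,9.051,0.583,0.047,0.886,0.022
GPR_0.75,WI,y2,37.738,10.202,0.592,0.049,0.859,0.026
GPR_Lasso,WI,y1,41.99,9.299,0.585,0.047,0.884,0.023
GPR_Lasso,WI,y2,37.958,10.251,0.592,0.048,0.858,0.026
GPR_Ridge,WI,y1,33.521,7.205,0.57,0.048,0.905,0.02
GPR_Ridge,WI,y2,33.701,8.817,0.594,0.049,0.888,0.02
UPDN_1,I,y1,133.047,7.442,0.695,0.024,0.373,0.055
UPDN_1,I,y2,99.26,11.279,0.711,0.021,0.402,0.05
UPDN_2,I,y1,95.62,7.786,0.669,0.025,0.409,0.053
UPDN_2,I,y2,75.986,11.879,0.691,0.019,0.389,0.051
UPDN_3,I,y1,97.618,6.255,0.687,0.023,0.389,0.064
UPDN_3,I,y2,72.15,9.406,0.698,0.017,0.397,0.051
UPDN_4,I,y1,102.29,7.787,0.679,0.02,0.346,0.061
UPDN_4,I,y2,74.66,12.035,0.7,0.014,0.356,0.057
MPDN_1,I,y1,111.247,23.885,0.662,0.044,0.766,0.04
MPDN_1,I,y2,102.691,23.825,0.668,0.044,0.758,0.043
MPDN_2,I,y1,98.646,21.658,0.653,0.046,0.782,0.041
MPDN_2,I,y2,90.899,21.828,0.643,0.046,0.771,0.04
MPDN_3,I,y1,96.984,21.958,0.66,0.046,0.766,0.042
MPDN_3,I,y2,89.359,22.391,0.638,0.047,0.769,0.041
MPDN_4,I,y1,94.62,21.06,0.651,0.046,0.779,0.039
MPDN_4,I,y2,85.397,21.374,0.632,0.047,0.78,0.038
GPR_0.5,I,y1,64.279,14.495,0.624,0.046,0.825,0.031
GPR_0.5,I,y2,48.417,10.777,0.623,0.048,0.783,0.04
GPR_0.25,I,y1,62.199,13.912,0.61,0.046,0.83,0.03
GPR_0.25,I,y2,46.086,10.418,0.621,0.048,0.787,0.04
GPR_0.75,I,y1,65.515,14.917,0.627,0.045,0.824,0.032
GPR_0.75,I,y2,49.455,11.066,0.624,0.048,0.781,0.039
GPR_Lasso,I,y1,67.005,15.7,0.628,0.046,0.82,0.033
GPR_Lasso,I,y2,50.073,11.395,0.624,0.048,0.78,0.04
GPR_Ridge,I,y1,116.056,22.719,0.788,0.049,0.857,0.028
GPR_Ridge,I,y2,86.785,18.019,0.775,0.049,0.826,0.032
"""

_DATASET2 = """\
model,interaction,trait,mse,se_mse,maape,se_maape,apc,se_apc
UPDN_1,WI,PTR,16.682,3.268,0.503,0.025,0.371,0.045
UPDN_1,WI,SB,9.640,0.816,0.408,0.019,0.408,0.029
UPDN_1,WI,SN,10.965,1.144,0.350,0.016,0.552,0.037
UPDN_2,WI,PTR,11.323,1.172,0.438,0.019,0.458,0.039
UPDN_2,WI,SB,8.244,0.671,0.383,0.021,0.449,0.041
UPDN_2,WI,SN,8.786,0.716,0.306,0.014,0.622,0.032
UPDN_3,WI,PTR,12.444,1.38,0.462,0.023,0.458,0.043
UPDN_3,WI,SB,7.833,0.562,0.379,0.016,0.467,0.044
UPDN_3,WI,SN,8.542,0.621,0.313,0.014,0.634,0.033
UPDN_4,WI,PTR,10.651,0.863,0.421,0.022,0.492,0.032
UPDN_4,WI,SB,7.382,0.493,0.373,0.018,0.487,0.038
UPDN_4,WI,SN,8.364,0.835,0.294,0.015,0.64,0.034
MPDN_1,WI,SN,8.287,0.815,0.300,0.015,0.644,0.031
MPDN_1,WI,PTR,11.433,0.892,0.438,0.019,0.514,0.034
MPDN_1,WI,SB,8.060,0.683,0.380,0.016,0.474,0.038
MPDN_2,WI,SN,8.362,0.816,0.292,0.015,0.649,0.031
MPDN_2,WI,PTR,10.523,0.791,0.429,0.019,0.538,0.033
MPDN_2,WI,SB,7.357,0.572,0.369,0.016,0.482,0.037
MPDN_3,WI,SN,8.312,0.790,0.304,0.015,0.656,0.030
MPDN_3,WI,PTR,10.252,0.801,0.420,0.019,0.544,0.033
MPDN_3,WI,SB,7.616,0.564,0.375,0.016,0.460,0.038
MPDN_4,WI,SN,8.233,0.796,0.278,0.015,0.653,0.030
MPDN_4,WI,PTR,10.371,0.778,0.422,0.019,0.528,0.033
MPDN_4,WI,SB,7.855,0.593,0.372,0.016,0.449,0.038
GPR_0.5,WI,SN,8.389,0.787,0.304,0.015,0.630,0.031
GPR_0.5,WI,PTR,10.139,0.769,0.408,0.019,0.535,0.033
GPR_0.5,WI,SB,7.168,0.555,0.371,0.016,0.482,0.037
GPR_0.25,WI,SN,8.384,0.786,0.304,0.015,0.631,0.031
GPR_0.25,WI,PTR,10.132,0.769,0.408,0.019,0.534,0.033
GPR_0.25,WI,SB,7.163,0.556,0.371,0.016,0.483,0.037
GPR_0.75,WI,SN,8.389,0.787,0.304,0.015,0.631,0.031
GPR_0.75,WI,PTR,10.140,0.769,0.408,0.019,0.535,0.033
GPR_0.75,WI,SB,7.170,0.555,0.371,0.016,0.482,0.037
GPR_Lasso,WI,SN,8.390,0.787,0.304,0.015,0.631,0.031
GPR_Lasso,WI,PTR,10.140,0.769,0.408,0.019,0.535,0.033
GPR_Lasso,WI,SB,7.171,0.556,0.371,0.016,0.482,0.037
GPR_Ridge,WI,SN,8.346,0.785,0.303,0.015,0.627,0.032
GPR_Ridge,WI,PTR,10.262,0.767,0.413,0.019,0.512,0.035
GPR_Ridge,WI,SB,7.159,0.552,0.372,0.016,0.479,0.038
UPDN_1,I,PTR,16.213,1.677,0.503,0.024,0.326,0.047
UPDN_1,I,SB,10.089,0.923,0.404,0.021,0.361,0.044
UPDN_1,I,SN,12.308,1.113,0.353,0.019,0.494,0.051
UPDN_2,I,PTR,13.014,1.308,0.45,0.018,0.391,0.046
UPDN_2,I,SB,9.448,0.766,0.382,0.016,0.396,0.046
UPDN_2,I,SN,10.923,1.016,0.322,0.014,0.562,0.038
UPDN_3,I,PTR,13.346,1.472,0.456,0.019,0.43,0.045
UPDN_3,I,SB,9.061,0.598,0.384,0.015,0.431,0.04
UPDN_3,I,SN,10.718,1.042,0.323,0.018,0.575,0.047
UPDN_4,I,PTR,12.421,1.364,0.434,0.021,0.441,0.046
UPDN_4,I,SB,8.028,0.62,0.372,0.016,0.451,0.039
UPDN_4,I,SN,9.317,0.913,0.309,0.019,0.62,0.035
MPDN_1,I,SN,11.878,1.120,0.338,0.014,0.535,0.035
MPDN_1,I,PTR,15.276,1.231,0.487,0.018,0.391,0.040
MPDN_1,I,SB,10.068,0.776,0.400,0.015,0.370,0.041
MPDN_2,I,SN,11.503,1.044,0.323,0.014,0.595,0.031
MPDN_2,I,PTR,12.745,1.017,0.440,0.018,0.473,0.037
MPDN_2,I,SB,9.341,0.718,0.379,0.015,0.427,0.038
MPDN_3,I,SN,9.942,0.896,0.310,0.015,0.585,0.033
MPDN_3,I,PTR,11.654,0.910,0.424,0.019,0.471,0.037
MPDN_3,I,SB,8.226,0.622,0.375,0.016,0.425,0.038
MPDN_4,I,SN,10.314,0.914,0.297,0.015,0.589,0.033
MPDN_4,I,PTR,12.018,0.933,0.418,0.019,0.462,0.036
MPDN_4,I,SB,8.245,0.616,0.373,0.016,0.423,0.039
GPR_0.5,I,SN,10.649,0.884,0.365,0.014,0.527,0.036
GPR_0.5,I,PTR,11.539,0.864,0.434,0.018,0.462,0.035
GPR_0.5,I,SB,8.482,0.622,0.400,0.016,0.347,0.040
GPR_0.25,I,SN,10.661,0.883,0.366,0.014,0.526,0.036
GPR_0.25,I,PTR,11.542,0.866,0.435,0.018,0.462,0.035
GPR_0.25,I,SB,8.488,0.623,0.400,0.016,0.347,0.040
GPR_0.75,I,SN,10.654,0.886,0.365,0.014,0.528,0.036
GPR_0.75,I,PTR,11.557,0.865,0.434,0.018,0.460,0.035
GPR_0.75,I,SB,8.475,0.621,0.400,0.016,0.347,0.040
GPR_Lasso,I,SN,10.652,0.886,0.365,0.014,0.528,0.036
GPR_Lasso,I,PTR,11.553,0.865,0.434,0.018,0.460,0.035
GPR_Lasso,I,SB,8.490,0.622,0.401,0.016,0.347,0.040
GPR_Ridge,I,SN,11.722,0.962,0.395,0.013,0.601,0.033
GPR_Ridge,I,PTR,11.986,0.885,0.438,0.018,0.503,0.035
GPR_Ridge,I,SB,8.444,0.659,0.386,0.015,0.461,0.038
"""


def dataset1_results() -> pd.DataFrame:
    """Per-trait benchmark metrics for data set 1 (182 lines, 2 traits)."""
    return pd.read_csv(io.StringIO(_DATASET1))


def dataset2_results() -> pd.DataFrame:
    """Per-trait benchmark metrics for data set 2 (438 lines, 3 traits)."""
    return pd.read_csv(io.StringIO(_DATASET2))


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up — the rounding convention of printed reports
    (numpy's banker's rounding would turn 50.5555 into 50.555, not 50.556)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def trait_average(results: pd.DataFrame, model: str, interaction: str, metric: str,
                  ndigits: int = 3) -> float:
    """Across-trait average of one model's metric, rounded as reported."""
    sub = results[(results["model"] == model) & (results["interaction"] == interaction)]
    if sub.empty:
        raise KeyError(f"no rows for model={model!r}, interaction={interaction!r}")
    return round_half_up(average_across_traits(sub[metric].to_numpy()), ndigits)


def headline_summary() -> dict:
    """Recompute the headline summary arithmetic from the per-trait tables.

    Averages are rounded half-up to 3 decimals; for the MSE comparison the
    best model's average is additionally rounded to 1 decimal, matching the
    convention of the reported ratios.
    """
    ds1, ds2 = dataset1_results(), dataset2_results()
    worst_mse = trait_average(ds1, "UPDN_1", "WI", "mse")  # 50.556
    best_mse = round_half_up(trait_average(ds1, "GPR_Ridge", "WI", "mse"), 1)  # 33.6
    worst_maape = trait_average(ds1, "UPDN_3", "WI", "maape")  # 0.652
    best_maape = trait_average(ds1, "GPR_Ridge", "WI", "maape")  # 0.582
    best_apc = trait_average(ds1, "GPR_Ridge", "WI", "apc")  # 0.897
    worst_apc = trait_average(ds1, "UPDN_1", "WI", "apc")  # 0.535
    return {
        "ds1_wi_worst_mse_average": worst_mse,
        "ds1_wi_best_mse_average": best_mse,
        "ds1_wi_mse_superiority_pct": percent_superiority(worst_mse, best_mse),
        "ds1_wi_maape_superiority_pct": percent_superiority(worst_maape, best_maape),
        "ds1_wi_apc_superiority_pct": (best_apc - worst_apc) * 100.0 / worst_apc,
        "ds2_wi_mpdn2_mse_average": trait_average(ds2, "MPDN_2", "WI", "mse"),
    }
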