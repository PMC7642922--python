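"""Core data containers for marker-based prediction of count phenotypes.

The experimental unit is a *line* (an inbred plant genotype) observed in one
or more *environments* (trial replicates).  Genotypes enter as a binary
marker matrix (alt-allele absence/presence), phenotypes as non-negative
integer counts for one or more traits per line x environment cell.  The
predictor matrix concatenates one-hot environment dummies, the observation's
marker vector and, optionally, every environment x marker product column
(the fixed-effect G x E expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype call


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass(frozen=True)
class MarkerMatrix:
    """Lines x markers genotype matrix with entries in {0, 1}.

    Missing calls may be carried as the sentinel ``-1`` until
    :func:`filter_markers` imputes them.
    """

    line_ids: tuple
    marker_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "line_ids", tuple(str(l) for l in self.line_ids))
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line ids in marker matrix")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker ids in marker matrix")
        if values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"marker matrix shape {values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"marker entry for line {self.line_ids[i]!r}, marker "
                f"{self.marker_ids[j]!r} is {values[i, j]}; must be 0, 1 or "
                f"{MISSING} (missing)"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def row(self, line_id: str) -> np.ndarray:
        return self.values[self.line_ids.index(str(line_id))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.marker_ids))
        df.insert(0, "line", list(self.line_ids))
        return df


@dataclass(frozen=True)
class PhenotypeTable:
    """Line x environment observations with T non-negative count traits."""

    data: pd.DataFrame  # columns: line, env, then one column per trait
    trait_names: tuple

    def __post_init__(self):
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        df = self.data.reset_index(drop=True)
        expected = ["line", "env", *self.trait_names]
        if list(df.columns) != expected:
            raise ValidationError(
                f"phenotype columns {list(df.columns)} != expected {expected}"
            )
        if len(self.trait_names) < 1:
            raise ValidationError("at least one trait is required")
        dup = df.duplicated(subset=["line", "env"])
        if dup.any():
            r = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate phenotype cell (line={r['line']!r}, env={r['env']!r})"
            )
        for t in self.trait_names:
            col = df[t]
            num = pd.to_numeric(col, errors="coerce")
            bad = num.isna() | (num < 0) | (num != np.floor(num))
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValidationError(
                    f"trait {t!r} at row {i} (line={df['line'][i]!r}, "
                    f"env={df['env'][i]!r}) has value {col[i]!r}; counts must "
                    "be non-negative integers"
                )
            df[t] = num.astype(np.int64)
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        object.__setattr__(self, "data", df)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def env_ids(self) -> tuple:
        return tuple(pd.unique(self.data["env"]))

    @property
    def line_ids(self) -> tuple:
        return tuple(pd.unique(self.data["line"]))

    def counts(self) -> np.ndarray:
        """n_obs x T matrix of counts in table row order."""
        return self.data[list(self.trait_names)].to_numpy(dtype=np.int64)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric predictor matrix aligned to a PhenotypeTable.

    Column groups: ``env`` (one-hot dummies), ``marker`` (0/1 genotypes of
    the observation's line) and ``interaction`` (env x marker products).
    """

    X: np.ndarray
    column_labels: tuple
    column_groups: tuple
    row_keys: tuple  # (line_id, env_id) per row

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        object.__setattr__(self, "column_groups", tuple(self.column_groups))
        object.__setattr__(self, "row_keys", tuple(map(tuple, self.row_keys)))
        if X.shape != (len(self.row_keys), len(self.column_labels)):
            raise ValidationError("design matrix shape mismatch")
        if len(self.column_groups) != len(self.column_labels):
            raise ValidationError("column group/label length mismatch")
        env_cols = [i for i, g in enumerate(self.column_groups) if g == "env"]
        if env_cols and not np.allclose(X[:, env_cols].sum(axis=1), 1.0):
            raise ValidationError("environment one-hot block rows must sum to 1")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "DesignMatrix":
        idx = np.asarray(idx)
        return DesignMatrix(
            self.X[idx],
            self.column_labels,
            self.column_groups,
            [self.row_keys[i] for i in idx],
        )

    def env_labels(self) -> np.ndarray:
        return np.array([k[1] for k in self.row_keys])


@dataclass(frozen=True)
class TraitMatrix:
    """n_obs x T integer count responses, row-aligned with a DesignMatrix."""

    Y: np.ndarray
    trait_names: tuple = field(default=())

    def __post_init__(self):
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValidationError("trait matrix must be 2-D (n_obs x T)")
        if not np.issubdtype(Y.dtype, np.integer):
            if not np.all(Y == np.floor(Y)):
                raise ValidationError("trait matrix must be integer-valued")
            Y = Y.astype(np.int64)
        if (Y < 0).any():
            raise ValidationError("trait matrix entries must be >= 0")
        object.__setattr__(self, "Y", Y.astype(np.int64))
        names = tuple(self.trait_names) or tuple(f"y{t+1}" for t in range(Y.shape[1]))
        if len(names) != Y.shape[1]:
            raise ValidationError("trait name count does not match columns")
        object.__setattr__(self, "trait_names", names)

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_phenotypes(path, trait_names=None) -> PhenotypeTable:
    """Read a phenotype CSV/TSV with header ``line,env,<trait...>``."""
    df = _read_table(path)
    if list(df.columns[:2]) != ["line", "env"]:
        raise ValidationError(
            f"phenotype file must start with columns line,env; got {list(df.columns[:2])}"
        )
    traits = list(trait_names) if trait_names is not None else list(df.columns[2:])
    missing = [t for t in traits if t not in df.columns]
    if missing:
        raise ValidationError(f"trait columns not in file: {missing}")
    return PhenotypeTable(df[["line", "env", *traits]], traits)


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    ph.data.to_csv(path, index=False)


def read_markers(path) -> MarkerMatrix:
    """Read a marker CSV/TSV: first column ``line``, then one column per marker.

    Entries must be 0 or 1; empty cells, ``NA`` and ``-1`` are treated as
    missing calls (sentinel ``-1``).
    """
    df = _read_table(path)
    line_col = df.columns[0]
    lines = df[line_col].astype(str).tolist()
    marker_ids = list(df.columns[1:])
    raw = df[marker_ids].to_numpy(dtype=object) if marker_ids else np.empty((len(lines), 0), dtype=object)
    values = np.empty(raw.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(raw):
        s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
        if s in ("", "NA", "nan", str(MISSING)):
            values[i, j] = MISSING
        elif s in ("0", "1"):
            values[i, j] = int(s)
        else:
            raise ValidationError(
                f"marker {marker_ids[j]!r} for line {lines[i]!r} is {s!r}; "
                "entries must be 0, 1 or missing"
            )
    return MarkerMatrix(lines, marker_ids, values)


def write_markers(m: MarkerMatrix, path) -> None:
    m.to_frame().to_csv(path, index=False)


def read_markers_vcf(path) -> MarkerMatrix:
    """Import a VCF as alt-allele presence/absence (0/1) per sample.

    Uses the GT field only; any called alternate allele codes 1, homozygous
    reference codes 0, missing calls keep the missing sentinel.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF import requires the optional dependency cyvcf2") from e

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, columns = [], []
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1]]
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = 1 if any(a > 0 for a in alleles) else 0
        marker_ids.append(vid)
        columns.append(col)
    values = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return MarkerMatrix(samples, marker_ids, values)


# ---------------------------------------------------------------------------
# marker QC


def filter_markers(m: MarkerMatrix, maf_min: float = 0.05, max_missing: float = 0.1) -> MarkerMatrix:
    """Drop low-MAF / high-missingness markers and impute the rest.

    A marker is kept when its minor-allele frequency (computed on observed
    calls) is >= ``maf_min`` and its missing fraction is <= ``max_missing``.
    Remaining missing calls are imputed by the observed allele frequency,
    thresholded at 0.5 back to {0, 1}.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must lie in [0, 0.5]; got {maf_min}")
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must lie in [0, 1]; got {max_missing}")
    values = m.values.copy()
    keep, imputed_cols = [], []
    for j in range(m.n_markers):
        col = values[:, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        miss_frac = 1.0 - n_obs / len(col)
        freq = float(col[obs].mean()) if n_obs else 0.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min or miss_frac > max_missing:
            continue
        if (~obs).any():
            col = col.copy()
            col[~obs] = 1 if freq >= 0.5 else 0
        keep.append(j)
        imputed_cols.append(col)
    if keep:
        new_values = np.stack(imputed_cols, axis=1)
    else:
        new_values = np.empty((m.n_lines, 0), dtype=np.int8)
    return MarkerMatrix(m.line_ids, [m.marker_ids[j] for j in keep], new_values)


# ---------------------------------------------------------------------------
# design construction


def build_design(
    ph: PhenotypeTable, m: MarkerMatrix, include_interaction: bool = False,
    env_order=None,
):
    """Build the predictor matrix ``[env one-hot | markers | env x marker]``.

    Returns ``(DesignMatrix, TraitMatrix)`` row-aligned with ``ph``.  The
    interaction block, when requested, is the columnwise Khatri-Rao product
    of the environment one-hot block and the marker block (one column per
    (env, marker) pair, environment-major order).  ``env_order`` fixes the
    dummy-column order (e.g. the order a model was trained with); an
    environment not in it is an error.
    """
    if (m.values == MISSING).any():
        raise ValidationError(
            "marker matrix contains missing calls; run filter_markers first"
        )
    line_index = {l: i for i, l in enumerate(m.line_ids)}
    unknown = [l for l in ph.line_ids if l not in line_index]
    if unknown:
        raise ValidationError(f"phenotype line {unknown[0]!r} not present in marker matrix")

    envs = list(ph.env_ids) if env_order is None else [str(e) for e in env_order]
    missing_envs = [e for e in ph.env_ids if e not in envs]
    if missing_envs:
        raise ValidationError(f"unknown environment id {missing_envs[0]!r}")
    env_pos = {e: k for k, e in enumerate(envs)}
    n, n_env, n_mark = ph.n_obs, len(envs), m.n_markers

    E = np.zeros((n, n_env))
    G = np.zeros((n, n_mark))
    row_keys = []
    for i, (line, env) in enumerate(zip(ph.data["line"], ph.data["env"])):
        E[i, env_pos[env]] = 1.0
        G[i] = m.values[line_index[line]]
        row_keys.append((line, env))

    labels = [f"env:{e}" for e in envs] + [f"marker:{mk}" for mk in m.marker_ids]
    groups = ["env"] * n_env + ["marker"] * n_mark
    blocks = [E, G]
    if include_interaction:
        inter = (E[:, :, None] * G[:, None, :]).reshape(n, n_env * n_mark)
        blocks.append(inter)
        labels += [f"gxe:{e}:{mk}" for e in envs for mk in m.marker_ids]
        groups += ["interaction"] * (n_env * n_mark)

    X = np.concatenate(blocks, axis=1) if blocks else np.empty((n, 0))
    design = DesignMatrix(X, labels, groups, row_keys)
    traits = TraitMatrix(ph.counts(), ph.trait_names)
    return design, traits
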