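"""Mother-child dyad data model, CSV I/O, and measurement preprocessing.

The unit of analysis is a mother paired with one of her children (a *dyad*),
carrying three substantive variables:

``iq_mother``
    Maternal IQ (AFQT rescaled to an IQ metric), possibly missing.
``iq_child``
    Child IQ (mean of available PIAT subtest scores, IQ metric), possibly
    missing.
``bf``
    Dichotomous breastfeeding indicator in {0, 1}, possibly missing.

Records in which all three substantive variables are missing carry no
information for any of the downstream models and are removed at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTANTIVE_COLUMNS",
    "DyadDataset",
    "read_dyads",
    "write_dyads",
    "derive_bf_indicator",
    "standardize_to_iq",
    "average_available_scores",
]

#: Canonical column order of the substantive variables.
SUBSTANTIVE_COLUMNS = ("bf", "iq_mother", "iq_child")

#: Default mapping of variable roles to CSV column names for child ``k``.
DEFAULT_COLUMN_MAP = {
    "id": "id",
    "iq_mother": "iq_mother",
    "iq_child1": "iq_child1",
    "iq_child2": "iq_child2",
    "bf_child1": "bf_child1",
    "bf_child2": "bf_child2",
}


@dataclass
class DyadDataset:
    """An ordered collection of mother-child dyad records.

    Parameters
    ----------
    df
        Frame with columns ``dyad_id``, ``bf``, ``iq_mother``, ``iq_child``.
        Missing values are NaN (``bf`` is stored as float for that reason).
    child_index
        Which child (1 or 2) the ``iq_child``/``bf`` columns refer to.
    provenance
        Free text describing the origin, e.g. ``"empirical"``, ``"synthetic"``
        or ``"subsample"``.
    """

    df: pd.DataFrame
    child_index: int = 1
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        missing_cols = [c for c in ("dyad_id", *SUBSTANTIVE_COLUMNS) if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"dataset frame lacks columns {missing_cols}")
        bf = self.df["bf"]
        bad_bf = bf.dropna()[~bf.dropna().isin((0.0, 1.0))]
        if len(bad_bf):
            raise ValueError(f"bf values outside {{0, 1, missing}}: {sorted(bad_bf.unique())[:5]}")
        all_missing = self.df[list(SUBSTANTIVE_COLUMNS)].isna().all(axis=1)
        if all_missing.any():
            raise ValueError(
                f"{int(all_missing.sum())} record(s) have all substantive fields missing; "
                "filter them before constructing the dataset (read_dyads does this)"
            )

    @property
    def n_total(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        """(n, 3) float array in canonical order (bf, iq_mother, iq_child)."""
        return self.df[list(SUBSTANTIVE_COLUMNS)].to_numpy(dtype=float)

    def observed_counts(self) -> dict[str, int]:
        """Per-variable count of non-missing values."""
        return {c: int(self.df[c].notna().sum()) for c in SUBSTANTIVE_COLUMNS}

    def subset(self, index: Sequence[int], provenance: str = "subsample") -> "DyadDataset":
        """Row subset by positional index, preserving order of ``index``."""
        return DyadDataset(
            self.df.iloc[list(index)].reset_index(drop=True),
            child_index=self.child_index,
            provenance=provenance,
        )

    def with_values(self, values: np.ndarray, provenance: Optional[str] = None) -> "DyadDataset":
        """Copy of the dataset with the substantive columns replaced."""
        df = self.df.copy()
        df[list(SUBSTANTIVE_COLUMNS)] = np.asarray(values, dtype=float)
        return DyadDataset(df, self.child_index, provenance or self.provenance)


def _drop_all_missing(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    keep = ~df[list(SUBSTANTIVE_COLUMNS)].isna().all(axis=1)
    return df[keep].reset_index(drop=True), int((~keep).sum())


def read_dyads(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    child_index: int = 1,
    na_values: Sequence[str] = ("",),
    provenance: str = "empirical",
) -> DyadDataset:
    """Read a dyad CSV for one child.

    ``column_map`` maps roles (``id``, ``iq_mother``, ``iq_child1``,
    ``bf_child1``, ``iq_child2``, ``bf_child2``) to the file's column names;
    unmapped roles fall back to the role name itself. Missing values are
    encoded by the ``na_values`` sentinels (empty cell by default). Records
    with all three substantive fields missing are removed; the removal count
    is retrievable via the returned dataset's provenance-independent
    ``n_total`` versus the raw file.

    Raises
    ------
    ValueError
        If a required mapped column is absent, an IQ cell is non-numeric, or
        a breastfeeding cell is outside {0, 1, missing}.
    """
    if child_index not in (1, 2):
        raise ValueError("child_index must be 1 or 2")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)

    roles = {
        "iq_mother": cmap["iq_mother"],
        "iq_child": cmap[f"iq_child{child_index}"],
        "bf": cmap[f"bf_child{child_index}"],
    }
    for role, col in roles.items():
        if col not in raw.columns:
            raise ValueError(f"column {col!r} (role {role}) not found in {path}")

    df = pd.DataFrame()
    id_col = cmap["id"]
    df["dyad_id"] = raw[id_col] if id_col in raw.columns else np.arange(len(raw))
    for role in ("bf", "iq_mother", "iq_child"):
        col = pd.to_numeric(raw[roles[role]], errors="coerce")
        bad = raw[roles[role]].notna() & col.isna()
        if bad.any():
            raise ValueError(
                f"non-numeric value(s) in column {roles[role]!r}, "
                f"e.g. {raw.loc[bad, roles[role]].iloc[0]!r}"
            )
        df[role] = col.astype(float)
    df = df[["dyad_id", "bf", "iq_mother", "iq_child"]]

    df, n_dropped = _drop_all_missing(df)
    dataset = DyadDataset(df, child_index=child_index, provenance=provenance)
    dataset.n_dropped_all_missing = n_dropped  # type: ignore[attr-defined]
    return dataset


def write_dyads(dataset: DyadDataset, path) -> None:
    """Write the dataset back to CSV (missing values as empty cells)."""
    dataset.df.to_csv(path, index=False, na_rep="")


def derive_bf_indicator(responses: Iterable[Optional[str]]) -> Optional[int]:
    """Dichotomize repeated yes/no breastfeeding reports.

    A mother was asked on up to nine occasions whether she breastfed the
    child at all. The child is classified as breastfed (1) if she answered
    "yes" at least once and never answered "no"; as not breastfed (0) if she
    answered "no" at least once; and as missing (None) if no response exists.
    A mother with both "yes" and "no" answers is classified 0: the
    never-answered-"no" clause dominates.

    The result is invariant to response order and to how many occasions are
    absent (None).
    """
    saw_yes = saw_no = False
    for r in responses:
        if r is None:
            continue
        token = str(r).strip().lower()
        if token == "yes":
            saw_yes = True
        elif token == "no":
            saw_no = True
        else:
            raise ValueError(f"malformed response token {r!r}; expected 'yes', 'no' or None")
    if saw_no:
        return 0
    if saw_yes:
        return 1
    return None


def standardize_to_iq(scores, mean: float = 100.0, sd: float = 15.0) -> np.ndarray:
    """Affinely rescale scores to an IQ metric (sample M = 100, SD = 15).

    Uses the population (divisor ``n``) standard deviation, matching the
    maximum-likelihood moment convention used throughout the package. Missing
    (NaN) entries are preserved. Because the map is affine, correlations with
    any other variable are unchanged.

    Raises
    ------
    ValueError
        If fewer than two non-missing values exist or their spread is zero.
    """
    x = np.asarray(scores, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least two non-missing scores to standardize")
    s = obs.std()  # ddof=0
    if not s > 0:
        raise ValueError("zero variance input; cannot rescale to SD 15")
    out = x.copy()
    m = obs.mean()
    out = mean + sd * (x - m) / s
    return out


def average_available_scores(scores) -> float:
    """Arithmetic mean of the non-missing entries; NaN if none exist."""
    x = np.asarray(scores, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        return math.nan
    return float(obs.mean())
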