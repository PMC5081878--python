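"""Test-day record editing, trait transforms, and fixed-effect classes.

Raw test-day records carry milk yield (kg), fat and protein content (%),
and somatic cell count (SCC, thousand cells/mL).  Before modelling, records
are range-edited, SCC is mapped to the base-2 somatic cell score (SCS),
component percentages are converted to kg yields, and each record is
assigned to its herd x year-month-of-test contemporary group (HYM), its
age-season-of-calving class (AS) and its herd-year-of-calving class (HY).
The AS and HY classes each carry a fixed Legendre-polynomial regression on
days in milk describing the population lactation curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Columns a raw test-day table must provide.
REQUIRED_COLUMNS = (
    "cow",
    "herd",
    "test_year",
    "test_month",
    "calving_year",
    "calving_month",
    "age_at_calving",
    "dim",
    "milk",
    "fat_pct",
    "protein_pct",
    "scc",
)

DIM_MIN, DIM_MAX = 5, 305


def scs_from_scc(scc):
    """Somatic cell score: SCS = log2(SCC / 100) + 3, SCC in 10^3 cells/mL.

    SCC = 100 maps to SCS = 3; each doubling of the count adds one score
    unit.  Nonpositive counts are rejected.
    """
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("SCC must be positive (10^3 cells/mL)")
    out = np.log2(scc / 100.0) + 3.0
    return out if out.ndim else float(out)


def scc_from_scs(scs):
    """Inverse transform: SCC = 100 * 2**(SCS - 3)."""
    scs = np.asarray(scs, dtype=float)
    out = 100.0 * np.power(2.0, scs - 3.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EditConfig:
    """Record-edit ranges (inclusive) and the minimum records-per-cow rule."""

    milk: tuple[float, float] = (3.0, 75.0)
    fat_pct: tuple[float, float] = (1.5, 8.0)
    protein_pct: tuple[float, float] = (1.0, 7.0)
    scc: tuple[float, float] = (1.0, 500.0)
    dim: tuple[float, float] = (float(DIM_MIN), float(DIM_MAX))
    age_at_calving: tuple[float, float] = (18.0, 36.0)
    min_records: int = 5


@dataclass
class EditReport:
    """Removal counts per rule, in application order."""

    n_input: int
    removed: dict[str, int]
    removed_min_records: int
    n_kept: int
    n_cows_kept: int

    def to_dict(self) -> dict:
        return asdict(self)


#: Range rules in the fixed application order.
_RANGE_RULES = ("milk", "fat_pct", "protein_pct", "scc", "dim", "age_at_calving")


def apply_edits(
    records: pd.DataFrame, config: EditConfig | None = None
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the record edits and derive modelled traits.

    Range filters run first, in a fixed order (milk, fat %, protein %, SCC,
    DIM, age at calving); a record is charged to the first rule it violates.
    Cows left with fewer than ``min_records`` surviving records are then
    removed entirely.  On the kept records ``scs``, ``fat_kg`` and
    ``protein_kg`` are (re)computed:  fat_kg = milk * fat_pct / 100, and
    likewise for protein.
    """
    config = config or EditConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing required column(s): {missing}")

    keep = np.ones(len(records), dtype=bool)
    removed: dict[str, int] = {}
    for rule in _RANGE_RULES:
        lo, hi = getattr(config, rule)
        vals = records[rule].to_numpy(dtype=float)
        bad = keep & ~((vals >= lo) & (vals <= hi))
        removed[rule] = int(bad.sum())
        keep &= ~bad

    kept = records.loc[keep].copy()
    counts = kept.groupby("cow")["cow"].transform("size")
    under = counts < config.min_records
    removed_min = int(under.sum())
    kept = kept.loc[~under].copy()

    kept["scs"] = scs_from_scc(kept["scc"].to_numpy(dtype=float))
    kept["fat_kg"] = kept["milk"] * kept["fat_pct"] / 100.0
    kept["protein_kg"] = kept["milk"] * kept["protein_pct"] / 100.0

    report = EditReport(
        n_input=len(records),
        removed=removed,
        removed_min_records=removed_min,
        n_kept=len(kept),
        n_cows_kept=int(kept["cow"].nunique()),
    )
    return kept.reset_index(drop=True), report


def quarter_season(month) -> np.ndarray:
    """Default season-of-calving rule: calendar quarters (Jan-Mar = 0, ...)."""
    return (np.asarray(month, dtype=int) - 1) // 3


@dataclass
class ClassAssignment:
    """Dense per-record fixed-effect class codes plus their level maps.

    ``hym`` = herd x year-month of test; ``as_class`` = age-at-calving
    class (one per month, 18..36) crossed with season of calving;
    ``hy_class`` = herd x year of calving.  Codes are assigned in order of
    first appearance, so they are invariant to relabelling identifiers.
    """

    hym: np.ndarray
    as_class: np.ndarray
    hy_class: np.ndarray
    hym_levels: list[tuple]
    as_levels: list[tuple]
    hy_levels: list[tuple]

    @property
    def n_hym(self) -> int:
        return len(self.hym_levels)

    @property
    def n_as(self) -> int:
        return len(self.as_levels)

    @property
    def n_hy(self) -> int:
        return len(self.hy_levels)

    def write_maps(self, path_prefix) -> None:
        for name in ("hym", "as", "hy"):
            levels = getattr(self, f"{name}_levels")
            with open(f"{path_prefix}{name}_classes.tsv", "w") as fh:
                fh.write("code\tlevel\n")
                for code, lv in enumerate(levels):
                    fh.write(f"{code}\t{'/'.join(str(x) for x in lv)}\n")


def _dense_code(keys: pd.Series) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(keys, sort=False)
    return codes.astype(np.int64), list(uniques)


def assign_classes(records: pd.DataFrame, season_rule=quarter_season) -> ClassAssignment:
    """Assign HYM, AS and HY classes to edited records.

    Ages at calving must already lie in 18..36 months (the edits guarantee
    it); with the default quarter season rule the AS cross has at most
    19 x 4 = 76 levels.
    """
    age = records["age_at_calving"].to_numpy(dtype=int)
    if age.min() < 18 or age.max() > 36:
        raise ValueError("age_at_calving outside 18..36 months; run apply_edits first")
    season = season_rule(records["calving_month"].to_numpy())

    hym_key = list(zip(records["herd"], records["test_year"], records["test_month"]))
    as_key = list(zip(age, season))
    hy_key = list(zip(records["herd"], records["calving_year"]))

    hym, hym_levels = _dense_code(pd.Series(hym_key))
    as_c, as_levels = _dense_code(pd.Series(as_key))
    hy, hy_levels = _dense_code(pd.Series(hy_key))
    return ClassAssignment(hym, as_c, hy, hym_levels, as_levels, hy_levels)


def legendre_covariates(dim, order: int) -> np.ndarray:
    """Normalised Legendre covariates of days in milk.

    DIM is mapped linearly from [5, 305] onto x in [-1, 1] and the first
    ``order`` orthonormal Legendre polynomials are evaluated:
    phi_k(x) = sqrt((2k + 1) / 2) P_k(x), so the basis is orthonormal under
    the standard L2 inner product on [-1, 1].  Returns shape ``(order,)``
    for scalar input, else ``(n, order)``.
    """
    d = np.asarray(dim, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any((d < DIM_MIN) | (d > DIM_MAX)):
        raise ValueError(f"days in milk outside [{DIM_MIN}, {DIM_MAX}]")
    x = 2.0 * (d - DIM_MIN) / (DIM_MAX - DIM_MIN) - 1.0
    out = np.empty((len(x), order))
    for k in range(order):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        out[:, k] = np.sqrt((2 * k + 1) / 2.0) * np.polynomial.legendre.legval(x, coef)
    return out[0] if scalar else out


def cows_per_sire(n_cows: int, n_sires: int) -> int:
    """Average progeny-group size, rounded to the nearest integer."""
    if n_sires <= 0:
        raise ValueError("need at least one sire")
    return round(n_cows / n_sires)


def describe_structure(records: pd.DataFrame, pedigree=None) -> dict:
    """Arithmetic summary of an edited record table (counts, means, SDs).

    With a pedigree (list of :class:`~tdgibbs.pedigree.PedigreeEntry`),
    sire/dam counts over the recorded cows and the mean progeny-group size
    are included.
    """
    out: dict[str, float | int] = {
        "n_records": len(records),
        "n_herds": int(records["herd"].nunique()),
        "n_cows": int(records["cow"].nunique()),
    }
    for trait in ("scs", "milk", "fat_kg", "protein_kg", "dim"):
        if trait in records:
            vals = records[trait].to_numpy(dtype=float)
            out[f"{trait}_mean"] = float(vals.mean())
            out[f"{trait}_sd"] = float(vals.std(ddof=1))
    if pedigree is not None:
        parents = {e.animal: (e.sire, e.dam) for e in pedigree}
        cows = records["cow"].unique()
        sires = {parents[c][0] for c in cows if c in parents} - {None}
        dams = {parents[c][1] for c in cows if c in parents} - {None}
        out["n_sires"] = len(sires)
        out["n_dams"] = len(dams)
        if sires:
            out["cows_per_sire"] = cows_per_sire(out["n_cows"], len(sires))
    return out
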