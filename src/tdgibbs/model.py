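"""Design information for the multi-trait fixed-regression animal model.

Each test-day record contributes, for all four traits jointly, one
herd-year-month (HYM) contemporary-group indicator, six Legendre covariates
nested in its age-season-of-calving class, five nested in its
herd-year-of-calving class, one additive-genetic (animal) effect and one
permanent-environment (cow) effect:

    y = HYM + sum_q beta_q z_q(t) + sum_q delta_q z_q(t) + a + pe + e

The :class:`ModelFrame` stores the dense level codes, the covariate values,
and a by-column sparse view of the fixed design that the Gibbs sampler
sweeps over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import RelationshipStructure
from .phenotypes import ClassAssignment, legendre_covariates

TRAITS = ("scs", "milk", "fat", "protein")
TRAIT_COLUMNS = ("scs", "milk", "fat_kg", "protein_kg")


def _group_csr(codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Record indices grouped by level: (indptr, record_index) like CSR."""
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=n_levels)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr.astype(np.int64), order.astype(np.int64)


@dataclass
class ModelFrame:
    """Per-record design of the four-trait test-day model."""

    y: np.ndarray  # (n_records, 4), trait order SCS, milk, fat, protein
    hym: np.ndarray
    as_class: np.ndarray
    hy_class: np.ndarray
    z_as: np.ndarray  # (n_records, as_order)
    z_hy: np.ndarray  # (n_records, hy_order)
    animal: np.ndarray  # index into rel.ids
    cow: np.ndarray  # dense cow code
    cow_ids: list
    rel: RelationshipStructure
    n_hym: int
    n_as: int
    n_hy: int

    # sampler views, filled by build_model_frame
    fix_indptr: np.ndarray = None
    fix_rows: np.ndarray = None
    fix_vals: np.ndarray = None
    fix_ss: np.ndarray = None
    pe_indptr: np.ndarray = None
    pe_rows: np.ndarray = None
    an_indptr: np.ndarray = None
    an_rows: np.ndarray = None
    cow_to_animal: np.ndarray = None  # animal index per cow code
    is_recorded: np.ndarray = None  # bool per animal

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def n_animals(self) -> int:
        return self.rel.n

    @property
    def as_order(self) -> int:
        return self.z_as.shape[1]

    @property
    def hy_order(self) -> int:
        return self.z_hy.shape[1]

    @property
    def n_fixed_columns(self) -> int:
        """HYM indicators plus one column per (class, coefficient) pair."""
        return self.n_hym + self.n_as * self.as_order + self.n_hy * self.hy_order

    def fixed_design(self) -> sparse.csc_matrix:
        """The fixed-effect design as a records x columns sparse matrix."""
        return sparse.csc_matrix(
            (self.fix_vals, self.fix_rows, self.fix_indptr),
            shape=(self.n_records, self.n_fixed_columns),
        )


def build_model_frame(
    records: pd.DataFrame,
    classes: ClassAssignment,
    rel: RelationshipStructure,
    as_order: int = 6,
    hy_order: int = 5,
) -> ModelFrame:
    """Assemble the :class:`ModelFrame` from edited, class-assigned records.

    ``records`` must carry the derived traits (``scs``, ``fat_kg``,
    ``protein_kg``) from :func:`~tdgibbs.phenotypes.apply_edits`; every
    recorded cow must exist in the pedigree behind ``rel``.  All four traits
    are required on every record.
    """
    n = len(records)
    y = records.loc[:, list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("all four traits must be observed (finite) on every record")

    missing = sorted({c for c in records["cow"] if c not in rel.index})
    if missing:
        shown = ", ".join(str(m) for m in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"recorded cows absent from pedigree: {shown}{more}")

    dim = records["dim"].to_numpy(dtype=float)
    z_as = legendre_covariates(dim, as_order)
    z_hy = legendre_covariates(dim, hy_order)

    animal = np.array([rel.index[c] for c in records["cow"]], dtype=np.int64)
    cow_codes, cow_ids = pd.factorize(records["cow"], sort=False)
    cow_codes = cow_codes.astype(np.int64)

    frame = ModelFrame(
        y=y,
        hym=classes.hym,
        as_class=classes.as_class,
        hy_class=classes.hy_class,
        z_as=z_as,
        z_hy=z_hy,
        animal=animal,
        cow=cow_codes,
        cow_ids=list(cow_ids),
        rel=rel,
        n_hym=classes.n_hym,
        n_as=classes.n_as,
        n_hy=classes.n_hy,
    )

    # by-column sparse fixed design: [HYM | AS class-major | HY class-major]
    rows = np.concatenate(
        [np.arange(n)] + [np.arange(n)] * as_order + [np.arange(n)] * hy_order
    )
    cols = [classes.hym]
    vals = [np.ones(n)]
    for q in range(as_order):
        cols.append(frame.n_hym + classes.as_class * as_order + q)
        vals.append(z_as[:, q])
    for q in range(hy_order):
        cols.append(frame.n_hym + frame.n_as * as_order + classes.hy_class * hy_order + q)
        vals.append(z_hy[:, q])
    design = sparse.coo_matrix(
        (np.concatenate(vals), (rows, np.concatenate(cols))),
        shape=(n, frame.n_fixed_columns),
    ).tocsc()
    frame.fix_indptr = design.indptr.astype(np.int64)
    frame.fix_rows = design.indices.astype(np.int64)
    frame.fix_vals = design.data.astype(np.float64)
    frame.fix_ss = np.asarray(design.multiply(design).sum(axis=0)).ravel()

    frame.pe_indptr, frame.pe_rows = _group_csr(cow_codes, frame.n_cows)
    frame.an_indptr, frame.an_rows = _group_csr(animal, rel.n)
    frame.cow_to_animal = np.full(frame.n_cows, -1, dtype=np.int64)
    frame.cow_to_animal[cow_codes] = animal
    frame.is_recorded = np.zeros(rel.n, dtype=np.bool_)
    frame.is_recorded[animal] = True
    return frame
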