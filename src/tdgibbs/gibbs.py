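"""Gibbs sampler for the (co)variance components of the test-day model.

One cycle sweeps every location effect (HYM, AS curve, HY curve, additive
genetic, permanent environment, in that fixed order) drawing each level's
4-trait subvector from its full conditional, then draws the three 4x4
covariance matrices from their inverted-Wishart full conditionals:

    G0 | a  ~ IW(a' A^{-1} a + S_g,  n_animals + nu_g)
    P0 | pe ~ IW(pe' pe     + S_p,  n_cows    + nu_p)
    R0 | e  ~ IW(e' e       + S_r,  n_records + nu_r)

Fixed effects carry flat priors.  The default covariance prior is flat
(uniform over symmetric matrices: nu_prior = -(traits + 1), zero scale), the
customary choice in the GIBBSxF90 family; inverted-Wishart scale/df priors
are configurable.  Beware near-zero-scale inverted-Wishart priors with
positive df: their density grows like |G|^(-(nu+p+1)/2) toward the origin
and can trap the chain in a zero-genetic-variance spike.
Every retained sample stores the 10 upper-triangle elements of each matrix
plus the cycle index; identical seed and configuration reproduce the chain
bit for bit, and periodic checkpoints carry the full generator state so a
resumed chain is identical to an uninterrupted one.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .model import ModelFrame, TRAITS

_N_TRAITS = 4
_TRIU = [(i, j) for i in range(_N_TRAITS) for j in range(i, _N_TRAITS)]


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = _sym(np.asarray(M, dtype=float))
    if M.shape != (_N_TRAITS, _N_TRAITS):
        raise ValueError(f"{name} must be {_N_TRAITS}x{_N_TRAITS}")
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} is not positive definite") from err
    return M


@dataclass
class CovarianceSet:
    """Additive (G0), permanent-environment (P0) and residual (R0) trait
    covariance matrices, trait order SCS, milk, fat, protein."""

    G0: np.ndarray
    P0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.G0 = _check_spd(self.G0, "G0")
        self.P0 = _check_spd(self.P0, "P0")
        self.R0 = _check_spd(self.R0, "R0")

    def copy(self) -> "CovarianceSet":
        return CovarianceSet(self.G0.copy(), self.P0.copy(), self.R0.copy())

    def flat(self) -> np.ndarray:
        """Upper triangles of G0, P0, R0 concatenated (30 values)."""
        return np.array(
            [m[i, j] for m in (self.G0, self.P0, self.R0) for i, j in _TRIU]
        )


def flat_names() -> list[str]:
    """Column names matching :meth:`CovarianceSet.flat`."""
    return [
        f"{m}_{TRAITS[i]}_{TRAITS[j]}" for m in ("g", "p", "r") for i, j in _TRIU
    ]


def _unflat(row: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mats = []
    k = 0
    for _ in range(3):
        M = np.zeros((_N_TRAITS, _N_TRAITS))
        for i, j in _TRIU:
            M[i, j] = M[j, i] = row[k]
            k += 1
        mats.append(M)
    return tuple(mats)  # type: ignore[return-value]


@dataclass
class GibbsConfig:
    """Chain-length bookkeeping and covariance priors.

    ``floor((chain_length - burn_in) / thin)`` samples are retained; e.g.
    200,000 cycles with 10,000 burn-in and a thinning interval of 10 keep
    19,000 samples.
    """

    chain_length: int = 200_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    prior_df: float = -(_N_TRAITS + 1)
    prior_scale: float = 0.0  # multiple of the identity
    checkpoint_every: int = 10_000
    joint_cow_blocks: bool = True

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class SampleStore:
    """Retained covariance samples: one row per sample, 30 columns + cycle."""

    cycles: np.ndarray
    samples: np.ndarray  # (n, 30)
    names: list[str] = field(default_factory=flat_names)

    def __len__(self) -> int:
        return len(self.cycles)

    def matrices(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(G0, P0, R0) of the k-th retained sample."""
        return _unflat(self.samples[k])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.names)
        df.insert(0, "cycle", self.cycles)
        return df

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "SampleStore":
        df = pd.read_csv(path)
        return cls(
            cycles=df["cycle"].to_numpy(dtype=np.int64),
            samples=df.drop(columns="cycle").to_numpy(dtype=float),
            names=[c for c in df.columns if c != "cycle"],
        )


def sample_inverse_wishart(S: np.ndarray, df: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from IW(S, df): invert a Wishart(df, S^{-1}) draw."""
    p = S.shape[0]
    if df <= p - 1:
        raise ValueError(f"inverse-Wishart degrees of freedom {df} <= dimension - 1")
    W = stats.wishart.rvs(df=df, scale=np.linalg.inv(S), random_state=rng)
    return _sym(np.linalg.inv(W))


def moment_start(frame: ModelFrame) -> CovarianceSet:
    """Diagonal method-of-moments starting values from the raw records.

    The within-cow variance (records minus their cow mean) starts R0; the
    between-cow variance, less the residual share of the cow means, starts
    the cow-level variance and is split evenly between G0 and P0.  Only the
    chain's transient depends on the start, but a start near the data's own
    variance decomposition keeps short chains nearly transient-free.
    """
    y = frame.y
    n_cows = frame.n_cows
    counts = np.bincount(frame.cow, minlength=n_cows).astype(float)
    means = np.zeros((n_cows, y.shape[1]))
    np.add.at(means, frame.cow, y)
    means /= counts[:, None]
    within = y - means[frame.cow]
    r = within.var(axis=0, ddof=1) * len(y) / max(1.0, len(y) - n_cows)
    k_bar = counts.mean()
    between = means.var(axis=0, ddof=1) - r / k_bar
    between = np.maximum(between, 0.05 * r)
    return CovarianceSet(np.diag(between / 2), np.diag(between / 2), np.diag(r))


class GibbsSampler:
    """Stateful Gibbs sampler over a :class:`~tdgibbs.model.ModelFrame`.

    The public surface is :func:`run_chain`; the sampler object itself is
    exposed so that the location sweep and the covariance draw can be tested
    and composed separately (e.g. location-only chains with covariances held
    fixed against a closed-form oracle).
    """

    def __init__(
        self,
        frame: ModelFrame,
        config: GibbsConfig,
        start: CovarianceSet | None = None,
    ) -> None:
        self.frame = frame
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        if start is None:
            start = moment_start(frame)
        self.covs = start.copy()
        self.u_fix = np.zeros((frame.n_fixed_columns, _N_TRAITS))
        self.u_pe = np.zeros((frame.n_cows, _N_TRAITS))
        self.u_an = np.zeros((frame.n_animals, _N_TRAITS))
        self.e = frame.y.astype(float).copy()
        self.cycle = 0
        self._ai = frame.rel.a_inv
        self._refresh_factors()

    # -- internal -----------------------------------------------------------
    def _refresh_factors(self) -> None:
        self._L_r = np.linalg.cholesky(self.covs.R0)
        self._R_inv = np.linalg.inv(self.covs.R0)
        self._G_inv = np.linalg.inv(self.covs.G0)
        self._P_inv = np.linalg.inv(self.covs.P0)

    # -- one-cycle pieces ---------------------------------------------------
    def sample_location_effects(self) -> None:
        """One Gauss-Seidel sweep of all location effects.

        Order: HYM, AS, HY (the fixed block), then the additive effects of
        unrecorded ancestors, then one joint (additive, permanent
        environment) 8-trait block per recorded cow.  The joint cow block
        is essential for mixing: the likelihood only identifies a + pe per
        cow, so separate single-site updates of the two effects are almost
        perfectly negatively correlated and barely move.  With
        ``joint_cow_blocks=False`` the sampler falls back to strictly
        single-level updates (animal then PE).
        """
        f = self.frame
        ai_indptr = self._ai.indptr.astype(np.int64)
        ai_idx = self._ai.indices.astype(np.int64)
        z_fix = self.rng.standard_normal((f.n_fixed_columns, _N_TRAITS))
        ok = _kernels.sweep_fixed(
            self.e, self.u_fix, f.fix_indptr, f.fix_rows, f.fix_vals, f.fix_ss,
            self._L_r, z_fix,
        )
        if self.config.joint_cow_blocks:
            z_an = self.rng.standard_normal((f.n_animals, _N_TRAITS))
            z_cow = self.rng.standard_normal((f.n_cows, 2 * _N_TRAITS))
            ok = ok and _kernels.sweep_animal(
                self.e, self.u_an, f.an_indptr, f.an_rows,
                ai_indptr, ai_idx, self._ai.data,
                self._R_inv, self._G_inv, z_an, f.is_recorded,
            )
            ok = ok and _kernels.sweep_cow_joint(
                self.e, self.u_an, self.u_pe, f.pe_indptr, f.pe_rows,
                f.cow_to_animal, ai_indptr, ai_idx, self._ai.data,
                self._R_inv, self._G_inv, self._P_inv, z_cow,
            )
        else:
            z_an = self.rng.standard_normal((f.n_animals, _N_TRAITS))
            z_pe = self.rng.standard_normal((f.n_cows, _N_TRAITS))
            ok = ok and _kernels.sweep_animal(
                self.e, self.u_an, f.an_indptr, f.an_rows,
                ai_indptr, ai_idx, self._ai.data,
                self._R_inv, self._G_inv, z_an,
                np.zeros(f.n_animals, dtype=np.bool_),
            )
            ok = ok and _kernels.sweep_iid(
                self.e, self.u_pe, f.pe_indptr, f.pe_rows,
                self._R_inv, self._P_inv, z_pe,
            )
        if not ok:
            raise np.linalg.LinAlgError(
                "singular conditional precision in location sweep"
            )

    def scatter_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Current (S_a, S_pe, S_e) cross-product matrices."""
        S_a = self.u_an.T @ (self._ai @ self.u_an)
        S_pe = self.u_pe.T @ self.u_pe
        S_e = self.e.T @ self.e
        return _sym(S_a), _sym(S_pe), _sym(S_e)

    def sample_covariances(self) -> None:
        f = self.frame
        c = self.config
        S_a, S_pe, S_e = self.scatter_matrices()
        prior = c.prior_scale * np.eye(_N_TRAITS)
        G0 = sample_inverse_wishart(S_a + prior, f.n_animals + c.prior_df, self.rng)
        P0 = sample_inverse_wishart(S_pe + prior, f.n_cows + c.prior_df, self.rng)
        R0 = sample_inverse_wishart(S_e + prior, f.n_records + c.prior_df, self.rng)
        self.covs = CovarianceSet(G0, P0, R0)
        self._refresh_factors()

    def step(self, update_covariances: bool = True) -> None:
        self.sample_location_effects()
        if update_covariances:
            self.sample_covariances()
        self.cycle += 1

    # -- checkpointing ------------------------------------------------------
    def save_state(self, path, cycles: list[int], rows: list[np.ndarray]) -> None:
        np.savez(
            path,
            u_fix=self.u_fix, u_pe=self.u_pe, u_an=self.u_an, e=self.e,
            G0=self.covs.G0, P0=self.covs.P0, R0=self.covs.R0,
            cycle=self.cycle,
            stored_cycles=np.asarray(cycles, dtype=np.int64),
            stored_rows=np.asarray(rows).reshape(len(rows), -1) if rows
            else np.zeros((0, 30)),
            rng_state=json.dumps(self.rng.bit_generator.state),
        )

    def load_state(self, path) -> tuple[list[int], list[np.ndarray]]:
        with np.load(path, allow_pickle=False) as ck:
            self.u_fix = ck["u_fix"]
            self.u_pe = ck["u_pe"]
            self.u_an = ck["u_an"]
            self.e = ck["e"]
            self.covs = CovarianceSet(ck["G0"], ck["P0"], ck["R0"])
            self.cycle = int(ck["cycle"])
            self.rng.bit_generator.state = json.loads(str(ck["rng_state"]))
            cycles = [int(x) for x in ck["stored_cycles"]]
            rows = [row.copy() for row in ck["stored_rows"]]
        self._refresh_factors()
        return cycles, rows


def run_chain(
    frame: ModelFrame,
    config: GibbsConfig,
    start: CovarianceSet | None = None,
    checkpoint_dir=None,
    resume: bool = False,
    log=None,
) -> SampleStore:
    """Run the full Gibbs chain and return the retained covariance samples.

    Covariance samples are stored every ``thin`` cycles after ``burn_in``.
    With ``checkpoint_dir`` the sampler writes its complete state (including
    the generator state) every ``checkpoint_every`` cycles; ``resume=True``
    picks up from the newest checkpoint and yields a chain bit-identical to
    an uninterrupted run.
    """
    sampler = GibbsSampler(frame, config, start=start)
    cycles: list[int] = []
    rows: list[np.ndarray] = []
    ck_path = None
    if checkpoint_dir is not None:
        ck_path = Path(checkpoint_dir)
        ck_path.mkdir(parents=True, exist_ok=True)
        if resume:
            saved = sorted(ck_path.glob("checkpoint_*.npz"))
            if saved:
                cycles, rows = sampler.load_state(saved[-1])

    t0 = time.time()
    while sampler.cycle < config.chain_length:
        sampler.step()
        c = sampler.cycle
        if c > config.burn_in and (c - config.burn_in) % config.thin == 0:
            cycles.append(c)
            rows.append(sampler.covs.flat())
        if ck_path is not None and c % config.checkpoint_every == 0:
            sampler.save_state(ck_path / f"checkpoint_{c:09d}.npz", cycles, rows)
        if log is not None and c % 10_000 == 0:
            log(f"cycle {c}/{config.chain_length} elapsed {time.time() - t0:.1f}s")

    return SampleStore(
        cycles=np.asarray(cycles, dtype=np.int64),
        samples=np.asarray(rows) if rows else np.zeros((0, 30)),
    )
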