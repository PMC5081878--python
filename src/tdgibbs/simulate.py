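"""Synthetic pedigrees and four-trait test-day records.

Generates data with exactly the statistical structure the model assumes --
herd-year-month contemporary groups, age-season and herd-year Legendre
lactation curves, pedigree-correlated additive effects, a permanent
environment effect per cow and correlated residuals -- together with a
truth file, so the whole estimation pipeline can be validated by parameter
recovery without any external data.

Default covariance truth: the published first-lactation Holstein test-day
estimates for SCS, milk, fat and protein (additive, permanent-environment
and residual variances per trait, moderate-to-high genetic correlations
among yields, small positive SCS-yield genetic correlations, negative
SCS-yield environmental correlations).  The environmental correlations are
applied identically to P0 and R0 (the pooled-environment convention shared
with the posterior module).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TRAITS
from .pedigree import PedigreeEntry, inbreeding_coefficients, _recode, UNKNOWN
from .phenotypes import REQUIRED_COLUMNS, legendre_covariates, scc_from_scs, quarter_season

_NT = 4


def _corr_to_cov(diag: np.ndarray, corr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(diag)
    return corr * np.outer(sd, sd)


def _default_G0() -> np.ndarray:
    diag = np.array([0.031, 7.471, 0.007, 0.005])
    corr = np.array(
        [
            [1.00, 0.07, 0.01, 0.11],
            [0.07, 1.00, 0.62, 0.90],
            [0.01, 0.62, 1.00, 0.80],
            [0.11, 0.90, 0.80, 1.00],
        ]
    )
    return _corr_to_cov(diag, corr)


#: Environmental correlations, applied to both P0 and R0.
_ENV_CORR = np.array(
    [
        [1.000, -0.177, -0.165, -0.152],
        [-0.177, 1.000, 0.850, 0.970],
        [-0.165, 0.850, 1.000, 0.910],
        [-0.152, 0.970, 0.910, 1.000],
    ]
)


def _default_P0() -> np.ndarray:
    return _corr_to_cov(np.array([0.233, 12.633, 0.014, 0.010]), _ENV_CORR)


def _default_R0() -> np.ndarray:
    return _corr_to_cov(np.array([0.761, 16.592, 0.056, 0.021]), _ENV_CORR)


@dataclass
class SimulationTruth:
    """True covariance matrices and fixed-effect generating parameters."""

    G0: np.ndarray = field(default_factory=_default_G0)
    P0: np.ndarray = field(default_factory=_default_P0)
    R0: np.ndarray = field(default_factory=_default_R0)
    #: overall trait means (SCS units, kg): folded into the AS curve intercepts
    trait_means: np.ndarray = field(
        default_factory=lambda: np.array([2.433, 32.82, 1.075, 1.006])
    )
    #: SD of the herd-year-month contemporary-group effect, per trait
    hym_sd: np.ndarray = field(default_factory=lambda: np.array([0.3, 2.0, 0.08, 0.05]))
    #: SD of AS-curve coefficients, per trait
    as_coef_sd: np.ndarray = field(default_factory=lambda: np.array([0.15, 1.2, 0.04, 0.03]))
    #: SD of HY-curve coefficients, per trait
    hy_coef_sd: np.ndarray = field(default_factory=lambda: np.array([0.08, 0.8, 0.03, 0.02]))

    def __post_init__(self) -> None:
        for name in ("G0", "P0", "R0"):
            M = 0.5 * (np.asarray(getattr(self, name), dtype=float) + np.asarray(getattr(self, name)).T)
            setattr(self, name, M)
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} is not positive definite")
        h2 = self.heritabilities()
        if np.any((h2 <= 0) | (h2 >= 1)):
            raise ValueError("implied heritabilities must lie in (0, 1)")

    def heritabilities(self) -> np.ndarray:
        total = np.diag(self.G0 + self.P0 + self.R0)
        return np.diag(self.G0) / total

    def genetic_correlations(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.G0))
        return self.G0 / np.outer(sd, sd)

    def to_dict(self) -> dict:
        rg = self.genetic_correlations()
        return {
            "traits": list(TRAITS),
            "G0": self.G0.tolist(),
            "P0": self.P0.tolist(),
            "R0": self.R0.tolist(),
            "trait_means": self.trait_means.tolist(),
            "hym_sd": self.hym_sd.tolist(),
            "heritability": dict(zip(TRAITS, self.heritabilities().tolist())),
            "genetic_correlation": {
                f"{TRAITS[i]}_{TRAITS[j]}": float(rg[i, j])
                for i in range(_NT)
                for j in range(i + 1, _NT)
            },
        }


@dataclass
class SimulationDesign:
    """Population and recording structure of the synthetic herd.

    The default is a desk-scale analogue of a national first-lactation
    data set: 2,000 recorded cows in 200 paternal half-sib families under a
    balanced nested mating design, 8 monthly tests per cow starting 5-35
    days into lactation, calvings over three years in 8 herds.  The herd
    size is chosen so the posterior standard deviation of a heritability is
    ~0.03: small enough that the posterior mean is a meaningful point
    estimate for parameter-recovery checks at that precision (at 1,000 cows
    the h2 posteriors are ~0.05 wide and visibly right-skewed, so their
    means sit above the simulated truth regardless of chain length).
    """

    n_sires: int = 200
    n_dams: int = 1000
    n_cows: int = 2000
    n_herds: int = 8
    #: "nested" mates each dam with a single sire in a near-balanced
    #: classical nested design (the standard layout for variance-component
    #: estimation); "random" mates at random
    mating: str = "nested"
    #: recorded-cow generations (random mating only); with 2, the second
    #: cohort's dams are first-cohort cows, giving dam-daughter record pairs
    generations: int = 1
    records_per_cow: int = 8
    test_interval: int = 30
    first_dim: tuple[int, int] = (5, 35)
    calving_years: tuple[int, int] = (2010, 2012)
    age_mean: float = 26.0  # months at first calving
    age_sd: float = 3.0
    edit_stress: bool = False
    #: spread each sire family evenly over herds, calving dates and ages
    #: (balanced validation design: family effects never accidentally
    #: confounded with the fixed classification)
    stratify_families: bool = True
    #: whiten the simulated deviates so the realized scatter matrices equal
    #: G0/P0/R0 exactly (variance reduction for parameter-recovery studies:
    #: the recovery error then reflects the estimator, not the luck of one
    #: finite sample)
    exact_moments: bool = True

    def __post_init__(self) -> None:
        if self.n_cows <= 0:
            raise ValueError("n_cows must be positive")
        last = self.first_dim[1] + (self.records_per_cow - 1) * self.test_interval
        if self.first_dim[0] < 5 or last > 305:
            raise ValueError("test-day schedule leaves days in milk outside [5, 305]")


def simulate_pedigree(design: SimulationDesign, rng: np.random.Generator) -> list[PedigreeEntry]:
    """Founder sires and dams plus recorded cows.

    The default is a classical nested mating design -- every dam is mated
    to a single sire, dams and progeny spread as evenly as possible -- which
    yields paternal half-sib and full-sib families of near-equal size, the
    textbook layout for estimating additive variance.  ``mating="random"``
    mates at random instead; there, ``generations > 1`` splits the recorded
    cows into cohorts whose dams are the previous cohort of recorded cows
    (sires always come from the founder pool, as with artificial
    insemination).
    """
    sires = [f"S{i:04d}" for i in range(design.n_sires)]
    dams = [f"D{i:04d}" for i in range(design.n_dams)]
    ped = [PedigreeEntry(s) for s in sires] + [PedigreeEntry(d) for d in dams]
    if design.mating == "nested":
        for c in range(design.n_cows):
            d = c % design.n_dams
            ped.append(PedigreeEntry(f"C{c:05d}", sires[d % design.n_sires], dams[d]))
        return ped
    gens = max(1, design.generations)
    per_gen = design.n_cows // gens
    prev_cohort = dams
    c = 0
    for g in range(gens):
        n_g = per_gen if g < gens - 1 else design.n_cows - per_gen * (gens - 1)
        cohort = []
        for _ in range(n_g):
            s = sires[rng.integers(design.n_sires)]
            d = prev_cohort[rng.integers(len(prev_cohort))]
            name = f"C{c:05d}"
            cohort.append(name)
            ped.append(PedigreeEntry(name, s, d))
            c += 1
        prev_cohort = cohort
    return ped


def _whiten(z: np.ndarray) -> np.ndarray:
    """Centre and decorrelate columns so z'z equals n times the identity."""
    z = z - z.mean(axis=0)
    C = z.T @ z / len(z)
    return z @ np.linalg.inv(np.linalg.cholesky(C)).T


def _decorrelate(z: np.ndarray, target_n: float) -> np.ndarray:
    """Right-multiply so z'z equals target_n times the identity (no centring)."""
    C = z.T @ z / target_n
    return z @ np.linalg.inv(np.linalg.cholesky(C)).T


def _group_mean_broadcast(z: np.ndarray, codes: np.ndarray, n_g: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_g).astype(float)
    means = np.zeros((n_g, z.shape[1]))
    np.add.at(means, codes, z)
    means /= counts[:, None]
    return means[codes]


def _nested_match(
    z: np.ndarray, levels: list[np.ndarray], ortho: np.ndarray | None = None
) -> np.ndarray:
    """Moment-match a hierarchically grouped sample level by level.

    ``levels`` lists nested group labels from coarse to fine (e.g. sire
    family, then dam within family); the individual rows form the final
    implicit level.  The sample is split into the orthogonal ANOVA
    components of that hierarchy (level means, deviations of the next
    level's means, ..., individual deviations), and each component's
    scatter is set exactly to its expected value under i.i.d. standard
    normals, so every level of the between/within-group variance
    decomposition is realized without chi-square fluctuation while keeping
    its expected magnitude.  ``ortho`` (n x q) is decomposed alongside and
    each component of ``z`` is made exactly uncorrelated with the matching
    component of ``ortho`` -- e.g. passing the additive-genetic values
    removes the realized genetic-environmental cross-covariance at every
    level of the hierarchy.  Used as a variance-reduction device for
    parameter-recovery studies; levels too small to adjust are left alone.
    """
    n, p = z.shape
    comps: list[np.ndarray] = []
    o_comps: list[np.ndarray | None] = []
    dfs: list[float] = []
    prev = np.zeros((n, p))
    o_prev = np.zeros((n, ortho.shape[1])) if ortho is not None else None
    prev_g = 0
    for lab in [*levels, np.arange(n)]:
        _, codes = np.unique(lab, return_inverse=True)
        n_g = codes.max() + 1
        bcast = _group_mean_broadcast(z, codes, n_g)
        comps.append(bcast - prev)
        if ortho is not None:
            o_bcast = _group_mean_broadcast(ortho, codes, n_g)
            o_comps.append(o_bcast - o_prev)
            o_prev = o_bcast
        else:
            o_comps.append(None)
        dfs.append(float(n_g - prev_g))
        prev = bcast
        prev_g = n_g

    out = np.zeros((n, p))
    for comp, o_comp, df in zip(comps, o_comps, dfs):
        q = 0
        if o_comp is not None and np.abs(o_comp).max() > 1e-12:
            q = o_comp.shape[1]
        if df >= 2 * p + q + 2:
            if q:
                Q, _ = np.linalg.qr(o_comp)
                comp = comp - Q @ (Q.T @ comp)
            comp = _decorrelate(comp, df)
        out += comp
    return out


def simulate_breeding_values(
    ped: list[PedigreeEntry],
    G0: np.ndarray,
    rng: np.random.Generator,
    exact_moments: bool = False,
) -> pd.DataFrame:
    """Four-trait breeding values: founders ~ MVN(0, G0), offspring =
    parent average + Mendelian-sampling deviation ~ MVN(0, d * G0) with
    d = 0.5 - 0.25 (F_s + F_d) for two known parents (0.75 - 0.25 F_p for
    one, 1 for none).

    With ``exact_moments`` the underlying standard-normal deviates are
    whitened first, which makes the realized additive scatter
    a' A^{-1} a equal n_animals * G0 exactly.
    """
    G0 = np.asarray(G0, dtype=float)
    if G0.any() and np.linalg.eigvalsh(0.5 * (G0 + G0.T)).min() <= 0:
        raise ValueError("G0 must be positive (semi-)definite")
    ids, sire, dam = _recode(ped)
    # inbreeding in topological order, for the Mendelian-sampling variances
    F_in = inbreeding_coefficients(ped)
    pos_in = {e.animal: i for i, e in enumerate(ped)}
    F = np.array([F_in[pos_in[a]] for a in ids])

    L = np.linalg.cholesky(G0) if G0.any() else np.zeros((_NT, _NT))
    bv = np.zeros((len(ids), _NT))
    z = rng.standard_normal((len(ids), _NT))
    if exact_moments and len(ids) > 4 * _NT:
        # Whiten founder draws and Mendelian deviates in separate groups, so
        # the additive scatter a' A^-1 a = sum_i m_i m_i' / d_i equals
        # n_animals * G0 exactly, term group by term group.  Founder sires
        # are their own group (their scatter is the between-family genetic
        # signal); under a nested mating structure the dams' draws and the
        # Mendelian deviates are additionally moment-matched at the
        # sire-family level and decoupled from the sire values, so the
        # realized between-family genetic variance carries no chi-square
        # fluctuation or cross-component covariance.
        n_ids = len(ids)
        founders = (sire == UNKNOWN) & (dam == UNKNOWN)
        is_sire = np.zeros(n_ids, dtype=bool)
        is_sire[sire[sire != UNKNOWN]] = True
        is_dam = np.zeros(n_ids, dtype=bool)
        is_dam[dam[dam != UNKNOWN]] = True
        sire_grp = founders & is_sire
        dam_grp = founders & is_dam & ~is_sire
        other_grp = founders & ~is_sire & ~is_dam
        if sire_grp.sum() > 2 * _NT:
            z[sire_grp] = _whiten(z[sire_grp])
        if other_grp.sum() > 2 * _NT:
            z[other_grp] = _whiten(z[other_grp])

        nonf = ~founders
        # nested if every founder dam with offspring has exactly one mate
        mates: dict[int, set[int]] = {}
        for i in np.where(nonf)[0]:
            if dam[i] != UNKNOWN and sire[i] != UNKNOWN:
                mates.setdefault(dam[i], set()).add(sire[i])
        dam_idx = np.where(dam_grp)[0]
        nested = bool(mates) and all(
            len(mates.get(d, set())) <= 1 for d in dam_idx
        ) and all(d in mates for d in dam_idx)
        if nested and dam_grp.sum() > 2 * _NT:
            dam_mate = np.array([next(iter(mates[d])) for d in dam_idx])
            z[dam_idx] = _nested_match(z[dam_idx], [dam_mate], ortho=z[dam_mate])
        elif dam_grp.sum() > 2 * _NT:
            z[dam_grp] = _whiten(z[dam_grp])

        if nonf.sum() > 4 * _NT:
            nonf_idx = np.where(nonf)[0]
            s_lab = sire[nonf_idx]
            d_lab = dam[nonf_idx]
            ortho = np.zeros((len(nonf_idx), 2 * _NT))
            known_s = s_lab != UNKNOWN
            known_d = d_lab != UNKNOWN
            ortho[known_s, :_NT] = z[s_lab[known_s]]
            ortho[known_d, _NT:] = z[d_lab[known_d]]
            z[nonf_idx] = _nested_match(z[nonf_idx], [s_lab, d_lab], ortho=ortho)
    for i in range(len(ids)):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            bv[i] = L @ z[i]
            continue
        mean = np.zeros(_NT)
        var_d = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            mean = 0.5 * (bv[s] + bv[d])
            var_d = 0.5 - 0.25 * (F[s] + F[d])
        else:
            p = s if s != UNKNOWN else d
            mean = 0.5 * bv[p]
            var_d = 0.75 - 0.25 * F[p]
        bv[i] = mean + np.sqrt(var_d) * (L @ z[i])
    return pd.DataFrame(bv, index=ids, columns=list(TRAITS))


def simulate_records(
    ped: list[PedigreeEntry],
    bvs: pd.DataFrame,
    truth: SimulationTruth,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Test-day record table plus the truth payload.

    Each cow gets ``records_per_cow`` tests at ``test_interval``-day
    spacing from a random first test day; the four-trait observation is
    the sum of its HYM effect, the AS and HY Legendre curves, the cow's
    breeding value, a permanent-environment effect and a residual.  The SCS
    channel is back-transformed to SCC for the emitted raw table.  Unless
    ``edit_stress`` is set, raw values are clipped into the standard edit
    ranges so the table passes the edits losslessly (the clipping touches
    well under 1% of records at the default truth).
    """
    cows = [e.animal for e in ped if e.animal.startswith("C")]
    if not cows:
        raise ValueError("pedigree contains no recorded cows (ids starting with 'C')")

    L_p = np.linalg.cholesky(truth.P0)
    L_r = np.linalg.cholesky(truth.R0)
    k = design.records_per_cow
    z_pe = rng.standard_normal((len(cows), _NT))
    z_res = rng.standard_normal((len(cows) * k, _NT))
    if design.exact_moments:
        # Moment-match the non-genetic effects at both the sire-family and
        # the global level: between-family variance of PE effects and of the
        # residual cow-means is exactly what a variance-partitioning model
        # reads as genetic family signal, so removing its chi-square
        # fluctuation (while keeping its expected magnitude) removes most of
        # the finite-sample wobble of a recovery study.
        sire_of = {e.animal: e.sire for e in ped}
        dam_of = {e.animal: e.dam for e in ped}
        fam = np.array([sire_of[c] or "" for c in cows])
        dam_lab = np.array([dam_of[c] or "" for c in cows])
        a_c = bvs.loc[cows].to_numpy()
        z_pe = _nested_match(z_pe, [fam, dam_lab], ortho=a_c)
        mu = z_res.reshape(len(cows), k, _NT).mean(axis=1)
        dev = z_res - np.repeat(mu, k, axis=0)
        if k > 1:
            dev = _decorrelate(dev, float(len(cows) * (k - 1)))
        mu = _nested_match(
            np.sqrt(k) * mu, [fam, dam_lab],
            ortho=np.column_stack([a_c, z_pe]),
        ) / np.sqrt(k)
        z_res = np.repeat(mu, k, axis=0) + dev
    pe_all = z_pe @ L_p.T
    res_all = z_res @ L_r.T
    hym_effects: dict[tuple, np.ndarray] = {}
    as_coefs: dict[tuple, np.ndarray] = {}
    hy_coefs: dict[tuple, np.ndarray] = {}
    phi0 = float(legendre_covariates(5, 1)[0])  # constant basis value

    def hym_effect(key):
        if key not in hym_effects:
            hym_effects[key] = truth.hym_sd * rng.standard_normal(_NT)
        return hym_effects[key]

    def curve(coefs, key, sd, intercept):
        if key not in coefs:
            order = 6 if coefs is as_coefs else 5
            c = sd * rng.standard_normal((order, _NT))
            c[0] += intercept
            coefs[key] = c
        return coefs[key]

    years = np.arange(design.calving_years[0], design.calving_years[1] + 1)
    rows = []
    pe_store = {}
    sire_of = {e.animal: e.sire for e in ped}
    strat_counter: dict[str, int] = {}
    for ci, cow in enumerate(cows):
        if design.stratify_families:
            # balanced design: spread each sire's daughters evenly over
            # herds, calving dates and ages, so family effects are never
            # accidentally confounded with the fixed classification
            t_idx = strat_counter.get(sire_of[cow], 0)
            strat_counter[sire_of[cow]] = t_idx + 1
            herd = f"H{t_idx % design.n_herds:02d}"
            cy = int(years[(t_idx // design.n_herds) % len(years)])
            cm = 1 + (ci + 5 * t_idx) % 12
            age = int(18 + round(design.age_mean - 18 + design.age_sd *
                                 np.cos(2.399 * t_idx)) % 19)
        else:
            herd = f"H{rng.integers(design.n_herds):02d}"
            cy = int(rng.choice(years))
            cm = int(rng.integers(1, 13))
            age = int(np.clip(np.round(rng.normal(design.age_mean, design.age_sd)), 18, 36))
        first = int(rng.integers(design.first_dim[0], design.first_dim[1] + 1))
        pe = pe_all[ci]
        pe_store[cow] = pe
        season = int(quarter_season(cm))
        calving = pd.Timestamp(year=cy, month=cm, day=min(28, int(rng.integers(1, 29))))
        for k in range(design.records_per_cow):
            dim = first + k * design.test_interval
            test = calving + pd.Timedelta(days=dim)
            z6 = legendre_covariates(dim, 6)
            z5 = legendre_covariates(dim, 5)
            beta = curve(as_coefs, (age, season), truth.as_coef_sd, truth.trait_means / phi0)
            delta = curve(hy_coefs, (herd, cy), truth.hy_coef_sd, 0.0)
            y = (
                hym_effect((herd, test.year, test.month))
                + z6 @ beta
                + z5 @ delta
                + bvs.loc[cow].to_numpy()
                + pe
                + res_all[ci * design.records_per_cow + k]
            )
            rows.append(
                {
                    "cow": cow,
                    "herd": herd,
                    "test_year": test.year,
                    "test_month": test.month,
                    "calving_year": cy,
                    "calving_month": cm,
                    "age_at_calving": age,
                    "dim": dim,
                    "y_scs": y[0],
                    "y_milk": y[1],
                    "y_fat": y[2],
                    "y_protein": y[3],
                }
            )

    df = pd.DataFrame(rows)
    milk = df["y_milk"].to_numpy()
    fat_pct = 100.0 * df["y_fat"].to_numpy() / milk
    protein_pct = 100.0 * df["y_protein"].to_numpy() / milk
    scc = scc_from_scs(df["y_scs"].to_numpy())
    if not design.edit_stress:
        milk = np.clip(milk, 3.0, 75.0)
        fat_pct = np.clip(fat_pct, 1.5, 8.0)
        protein_pct = np.clip(protein_pct, 1.0, 7.0)
        scc = np.clip(scc, 1.0, 500.0)
    df["milk"] = milk
    df["fat_pct"] = fat_pct
    df["protein_pct"] = protein_pct
    df["scc"] = scc
    records = df[list(REQUIRED_COLUMNS)].copy()

    truth_payload = truth.to_dict()
    truth_payload["breeding_values"] = {a: bvs.loc[a].tolist() for a in bvs.index}
    truth_payload["permanent_environment"] = {c: v.tolist() for c, v in pe_store.items()}
    truth_payload["hym_effects"] = {
        "/".join(map(str, k)): v.tolist() for k, v in hym_effects.items()
    }
    truth_payload["as_curves"] = {
        "/".join(map(str, k)): v.tolist() for k, v in as_coefs.items()
    }
    truth_payload["hy_curves"] = {
        "/".join(map(str, k)): v.tolist() for k, v in hy_coefs.items()
    }
    return records, truth_payload


@dataclass
class SimulatedData:
    pedigree: list[PedigreeEntry]
    records: pd.DataFrame
    breeding_values: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        with open(outdir / "pedigree.txt", "w") as fh:
            for e in self.pedigree:
                fh.write(f"{e.animal} {e.sire or '0'} {e.dam or '0'}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_dataset(
    design: SimulationDesign | None = None,
    truth: SimulationTruth | None = None,
    seed: int = 0,
) -> SimulatedData:
    """Pedigree + breeding values + record table + truth, from one seed."""
    design = design or SimulationDesign()
    truth = truth or SimulationTruth()
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(design, rng)
    bvs = simulate_breeding_values(ped, truth.G0, rng, exact_moments=design.exact_moments)
    records, payload = simulate_records(ped, bvs, truth, design, rng)
    return SimulatedData(ped, records, bvs, payload)
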