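"""Synthetic cohort generator with known ground truth.

The original study's raw data (461 individuals x 380 antigens, plus a rich
clinical table) is access-restricted, so every downstream stage is exercised
on synthetic data that emulates its structure:

* per-sample background level and scale (lognormal across samples), so the
  median/MAD normalization has real work to do;
* per-antigen baseline reactivity spread across antigens that is much wider
  than the within-antigen noise.  After per-sample median centering, each
  antigen's score vector is then near-atomic: most antigens sit cleanly
  inside one score bin, a minority straddle the zero boundary and become the
  rare very-prevalent reactivities — reproducing the left-skewed
  per-antigen seropositive-count shape seen in real bead-array serology;
* sparse heavy-tailed seropositive spikes (a Lomax tail on top of a +5
  sample-scale displacement), at per-antigen rates drawn from a lognormal
  with a point mass at zero, so per-individual true counts are
  approximately normal around ``spike_rate * n_antigens`` (25 by default)
  while per-antigen counts are right-skewed;
* a symptom table with planted antibody-symptom associations whose realized
  contingency tables satisfy configured margins by construction, plus
  independent distractor symptoms, clinical covariates and cytokines with
  missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

CYTOKINES = ("IL4", "IL6", "IL8", "IL10", "CuZnSOD")
CLINICAL_VARS = ("female", "affective_disorder", "fh_obesity",
                 "fh_psych_other", "fh_heart_disease", "clozapine",
                 "antidepressants")


class InfeasiblePlantError(ValueError):
    """Planted margins cannot be satisfied with the drawn cohort."""


@dataclass
class PlantedMargins:
    """Margins every planted pair must exceed; must be strictly stronger than
    the selection thresholds they are planted against (10 / 0.85 / 1.25)."""

    min_positives: int = 12
    min_prevalence_pos: float = 0.95
    min_prevalence_ratio: float = 2.0

    def validate(self) -> None:
        if not (self.min_positives > 10):
            raise ValueError("planted min_positives must exceed 10")
        if not (0.85 < self.min_prevalence_pos <= 1.0):
            raise ValueError("planted prevalence must exceed 0.85")
        if not (self.min_prevalence_ratio > 1.25):
            raise ValueError("planted prevalence ratio must exceed 1.25")


@dataclass
class CohortConfig:
    n_individuals: int = 461
    n_antigens: int = 380
    # per-sample background: location ~ LogN(log(loc), loc_sigma), scale likewise
    background_location: tuple[float, float] = (800.0, 0.3)
    background_scale: tuple[float, float] = (120.0, 0.25)
    #: expected fraction of seropositive cells over the whole matrix
    spike_rate: float = 25.0 / 380.0
    #: (minimum displacement, Lomax shape, Lomax scale) in sample-scale units
    spike_effect: tuple[float, float, float] = (5.0, 1.5, 8.0)
    #: sd of antigen baseline reactivity (sample-scale units)
    antigen_baseline_sd: float = 1.0
    #: within-antigen noise sd; must stay well below antigen_baseline_sd
    noise_sd: float = 0.08
    #: fraction of antigens with zero spike probability (never truly reactive)
    zero_reactivity_fraction: float = 0.18
    #: lognormal sigma of per-antigen spike rates (right-skews antigen counts)
    antigen_rate_sigma: float = 1.25
    n_symptoms: int = 205
    n_planted: int = 6
    planted_margins: PlantedMargins = field(default_factory=PlantedMargins)
    #: spike probability used for planted antigens (keeps their group size
    #: comfortably above the planted min_positives margin)
    planted_spike_rate: float = 0.08
    missing_rate: float = 0.02
    female_fraction: float = 0.39
    #: >0 plants a "high count in females" effect (relative rate increase)
    sex_count_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_antigens, self.n_symptoms) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.spike_rate < 1):
            raise ValueError("spike_rate must be in [0, 1)")
        if self.n_planted < 0 or self.n_planted > min(self.n_antigens,
                                                      self.n_symptoms):
            raise ValueError("n_planted out of range")
        if self.spike_effect[0] < 5.0:
            raise ValueError("spike displacement support must start at >= 5")
        if self.n_planted > 0:
            self.planted_margins.validate()


@dataclass
class SyntheticCohort:
    mfi: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame                      # binary, same shape as mfi
    planted_pairs: list[tuple[str, str]]     # (antigen_id, symptom_id)
    config: CohortConfig

    @property
    def symptom_columns(self) -> list[str]:
        return [c for c in self.clinical.columns if c.startswith("sym_")]

    def write(self, outdir) -> None:
        """MFI and clinical as CSV (ids in first column), truth as JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mfi.to_csv(out / "mfi.csv", index_label="individual_id")
        self.clinical.to_csv(out / "clinical.csv", index_label="individual_id")
        (out / "truth.json").write_text(json.dumps({
            "planted_pairs": self.planted_pairs,
            "seropositive": {a: self.truth.index[self.truth[a] == 1].tolist()
                             for a in self.truth.columns},
        }))


def _antigen_spike_rates(cfg: CohortConfig, rng: np.random.Generator,
                         planted_idx: np.ndarray) -> np.ndarray:
    """Per-antigen spike probabilities: a zero-rate block plus a lognormal
    spread, rescaled so the matrix-wide expectation equals ``spike_rate``."""
    q = np.zeros(cfg.n_antigens)
    if cfg.spike_rate == 0:
        return q
    n_zero = int(round(cfg.zero_reactivity_fraction * cfg.n_antigens))
    order = rng.permutation(cfg.n_antigens)
    order = order[~np.isin(order, planted_idx)]
    active = np.setdiff1d(np.arange(cfg.n_antigens),
                          np.concatenate([order[:n_zero], planted_idx]))
    raw = rng.lognormal(mean=0.0, sigma=cfg.antigen_rate_sigma,
                        size=active.size)
    budget = cfg.spike_rate * cfg.n_antigens - cfg.planted_spike_rate * planted_idx.size
    budget = max(budget, 0.0)
    if active.size and raw.sum() > 0:
        q[active] = np.minimum(raw / raw.sum() * budget, 0.75)
    q[planted_idx] = cfg.planted_spike_rate
    return q


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (MFI + clinical + ground truth).

    Deterministic given the config (including its seed).  Raises
    :class:`InfeasiblePlantError` if a planted antigen's realized truth group
    is smaller than the planted margin requires — an explicit failure rather
    than a silent retry.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_antigens

    individual_ids = [f"ind_{i:04d}" for i in range(n)]
    antigen_ids = [f"ag_{j:04d}" for j in range(m)]

    planted_idx = (rng.choice(m, size=cfg.n_planted, replace=False)
                   if cfg.n_planted else np.array([], dtype=int))

    # sample background level/scale, antigen baselines
    loc_mu, loc_sig = cfg.background_location
    sc_mu, sc_sig = cfg.background_scale
    level = rng.lognormal(np.log(loc_mu), loc_sig, size=n)
    scale = rng.lognormal(np.log(sc_mu), sc_sig, size=n)
    baseline = rng.normal(0.0, cfg.antigen_baseline_sd, size=m)
    # planted antigens sit mid-bin (background safely inside score 0.1),
    # so their realized calls equal truth
    baseline[planted_idx] = 0.7

    # ground-truth seropositivity
    q = _antigen_spike_rates(cfg, rng, planted_idx)
    rate = np.tile(q, (n, 1))
    if cfg.sex_count_effect:
        female = rng.random(n) < cfg.female_fraction
        rate = rate * np.where(female, 1.0 + cfg.sex_count_effect, 1.0)[:, None]
        rate = np.minimum(rate, 0.95)
    else:
        female = rng.random(n) < cfg.female_fraction
    truth = (rng.random((n, m)) < rate).astype(int)

    # heavy-tailed displacement for seropositive cells, in sample-scale units
    d_min, d_shape, d_scale = cfg.spike_effect
    disp = np.zeros((n, m))
    k = int(truth.sum())
    if k:
        disp[truth == 1] = d_min + d_scale * rng.pareto(d_shape, size=k)

    noise = rng.normal(0.0, cfg.noise_sd, size=(n, m))
    mfi_vals = level[:, None] + scale[:, None] * (baseline[None, :] + noise + disp)
    mfi_vals = np.maximum(mfi_vals, 0.0)

    mfi = pd.DataFrame(mfi_vals, index=individual_ids, columns=antigen_ids)
    truth_df = pd.DataFrame(truth, index=individual_ids, columns=antigen_ids)

    clinical, planted_pairs = _build_clinical(cfg, rng, truth_df,
                                              planted_idx, female,
                                              individual_ids, antigen_ids)
    return SyntheticCohort(mfi=mfi, clinical=clinical, truth=truth_df,
                           planted_pairs=planted_pairs, config=cfg)


def _build_clinical(cfg, rng, truth_df, planted_idx, female,
                    individual_ids, antigen_ids):
    n = cfg.n_individuals
    clinical = pd.DataFrame(index=individual_ids)
    clinical["female"] = female.astype(int)
    base_prev = {"affective_disorder": 0.30, "fh_obesity": 0.20,
                 "fh_psych_other": 0.25, "fh_heart_disease": 0.20,
                 "clozapine": 0.15, "antidepressants": 0.40}
    for var, prev in base_prev.items():
        clinical[var] = (rng.random(n) < prev).astype(int)
    for cyt in CYTOKINES:
        clinical[cyt] = rng.lognormal(mean=1.0, sigma=0.8, size=n)

    # distractor symptoms: independent Bernoulli, prevalence capped below the
    # symptom-prevalence criterion so they cannot trivially pass it
    sym_ids = [f"sym_{s:03d}" for s in range(cfg.n_symptoms)]
    prev = rng.uniform(0.05, 0.70, size=cfg.n_symptoms)
    sym = (rng.random((n, cfg.n_symptoms)) < prev[None, :]).astype(float)

    # planted pairs: assign symptom status deterministically from truth so the
    # realized table satisfies the margins exactly
    margins = cfg.planted_margins
    planted_pairs: list[tuple[str, str]] = []
    planted_sym_cols: list[int] = []
    sym_slots = rng.choice(cfg.n_symptoms, size=len(planted_idx), replace=False) \
        if len(planted_idx) else np.array([], dtype=int)
    for a_idx, s_idx in zip(planted_idx, sym_slots):
        a_id, s_id = antigen_ids[a_idx], sym_ids[s_idx]
        pos = np.flatnonzero(truth_df[a_id].to_numpy() == 1)
        neg = np.flatnonzero(truth_df[a_id].to_numpy() == 0)
        if pos.size < margins.min_positives:
            raise InfeasiblePlantError(
                f"planted antigen {a_id}: realized truth group {pos.size} "
                f"< required {margins.min_positives}")
        k_pos = int(np.ceil(margins.min_prevalence_pos * pos.size))
        prev_neg = margins.min_prevalence_pos / margins.min_prevalence_ratio
        k_neg = int(np.floor(prev_neg * neg.size))
        col = np.zeros(n)
        col[rng.permutation(pos)[:k_pos]] = 1
        col[rng.permutation(neg)[:k_neg]] = 1
        sym[:, s_idx] = col
        planted_pairs.append((a_id, s_id))
        planted_sym_cols.append(int(s_idx))

    # Generator contract: distractor pairs stay below the symptom-prevalence
    # selection margin.  Independent Bernoulli draws almost always satisfy
    # this, but across ~hundreds of antigens x hundreds of symptoms a rare
    # fluke can push a distractor's prevalence inside a truth-positive group
    # past the margin; flip just enough of those entries to zero.  Flips only
    # lower prevalences, so a single pass converges.  The 0.80 ceiling keeps
    # slack below the 0.85 criterion for the later MCAR removal of entries.
    distractor_cols = np.setdiff1d(np.arange(cfg.n_symptoms),
                                   np.array(planted_sym_cols, dtype=int))
    truth_np = truth_df.to_numpy()
    ceiling = 0.80
    for a_idx in range(truth_np.shape[1]):
        pos = np.flatnonzero(truth_np[:, a_idx] == 1)
        if pos.size < 10:
            continue
        max_allowed = int(np.floor(ceiling * pos.size))
        counts = sym[np.ix_(pos, distractor_cols)].sum(axis=0)
        for s_idx, c in zip(distractor_cols[counts > max_allowed],
                            counts[counts > max_allowed]):
            carriers = pos[sym[pos, s_idx] == 1]
            flip = rng.choice(carriers, size=int(c) - max_allowed,
                              replace=False)
            sym[flip, s_idx] = 0.0

    symdf = pd.DataFrame(sym, index=individual_ids, columns=sym_ids)

    # missing completely at random, planted symptom columns kept complete so
    # planted margins hold exactly on pairwise-complete tables
    if cfg.missing_rate > 0:
        mask = rng.random(symdf.shape) < cfg.missing_rate
        mask[:, planted_sym_cols] = False
        symdf = symdf.mask(mask)
        for col in list(base_prev) + list(CYTOKINES):
            miss = rng.random(n) < cfg.missing_rate
            clinical.loc[miss, col] = np.nan

    return pd.concat([clinical, symdf], axis=1), planted_pairs


# ---------------------------------------------------------------------------
# planar pools


@dataclass
class PlanarPoolSet:
    signals: pd.DataFrame            # pools x antigens, raw intensities
    truth: dict[str, list[str]]      # pool -> planted hit antigens

    @property
    def planted_union(self) -> set:
        return set().union(*self.truth.values()) if self.truth else set()


def generate_planar_pools(n_pools: int, n_antigens: int, n_hits_per_pool: int,
                          seed: int, unique_fraction: float = 0.89,
                          bulk_loc: float = 1000.0, bulk_sd: float = 100.0
                          ) -> PlanarPoolSet:
    """Per-pool Gaussian bulk signals with planted hits far above the bulk.

    Hits are displaced by (15 + Exp(5)) bulk SDs, which stays at or above the
    8-SD selection threshold even after the hits themselves inflate the
    pool's sample SD.  ``unique_fraction`` is the target fraction of the
    *union* panel detected in exactly one pool; with shared hits appearing
    in pool pairs this needs u = f*h/(2-f) unique hits per pool.  Fails if
    the hits would destabilize the bulk statistics (> 0.5% of antigens).
    """
    if n_hits_per_pool >= n_antigens:
        raise ValueError("n_hits_per_pool must be smaller than n_antigens")
    if n_hits_per_pool > 0.005 * n_antigens:
        raise ValueError("too many hits per pool to keep bulk statistics "
                         "stable (limit 0.5% of antigens)")
    rng = np.random.default_rng(seed)
    pool_ids = [f"pool_{p}" for p in range(n_pools)]
    antigen_ids = [f"pa_{j:05d}" for j in range(n_antigens)]
    signals = rng.normal(bulk_loc, bulk_sd, size=(n_pools, n_antigens))

    n_unique = int(round(unique_fraction * n_hits_per_pool
                         / (2.0 - unique_fraction)))
    n_unique = min(n_unique, n_hits_per_pool)
    n_shared = n_hits_per_pool - n_unique
    perm = rng.permutation(n_antigens)
    take = 0
    hits: dict[str, list[int]] = {p: [] for p in pool_ids}
    for p in pool_ids:
        hits[p].extend(perm[take:take + n_unique])
        take += n_unique
    # shared hits: each shared antigen appears in a pair of adjacent pools
    shared_slots = [(p, s) for s in range(n_shared) for p in pool_ids]
    for i in range(0, len(shared_slots) - 1, 2):
        a = perm[take]
        take += 1
        for p, _ in (shared_slots[i], shared_slots[i + 1]):
            hits[p].append(a)
    if len(shared_slots) % 2:
        a = perm[take]
        take += 1
        hits[shared_slots[-1][0]].append(a)

    for pi, p in enumerate(pool_ids):
        for j in hits[p]:
            signals[pi, j] = bulk_loc + (15.0 + rng.exponential(5.0)) * bulk_sd

    frame = pd.DataFrame(signals, index=pool_ids, columns=antigen_ids)
    truth = {p: sorted(antigen_ids[j] for j in hits[p]) for p in pool_ids}
    return PlanarPoolSet(signals=frame, truth=truth)
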