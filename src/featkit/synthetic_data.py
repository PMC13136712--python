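"""Synthetic KO and BE datasets with the statistical structure the models
assume.

The KO simulator emulates a genome-wide off-target screen: for each guide a
set of candidate sites at 0-6 mismatches, read counts that decay
exponentially with the (seed-weighted) mismatch burden, negative-binomial
sequencing noise, and ~97% of sites inactive at the count threshold. Site
abundance rises steeply with the allowed mismatch count, mirroring
enumeration of near-matches in a large genome.

The BE simulator emulates a proliferation screen read out as z-scores:
per-position nucleotide effects concentrated in the PAM-proximal region,
optional 3-mer motif effects, Gaussian noise, and an affine calibration
pinning the z < -2 tail mass.

All randomness flows from a single integer seed through one counter-based
stream per guide, so a guide's records do not depend on how many other
guides are simulated.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from featkit.core_io import (
    DNA_BASES,
    GAP,
    BEScreenRecord,
    DatasetTable,
    PairedSiteRecord,
)

PROTOSPACER_LEN = 20
PAM = "GG"  # fixed NGG-style PAM at positions 22-23; position 21 is random


class DegenerateVarianceError(ValueError):
    """The simulated z-scores have (near-)zero variance and cannot be
    calibrated to a target tail mass."""


@dataclasses.dataclass
class KOSimParams:
    """Knockout-screen simulation parameters.

    ``beta0`` is the baseline natural-log read count of a perfect match;
    each mismatch subtracts ``beta_mm`` (twice that inside the seed region,
    positions 13-20, via ``seed_penalty_multiplier``). ``dispersion`` is the
    negative-binomial size parameter (smaller = heavier tail).
    ``prevalence_active`` is the target fraction of sites whose count
    exceeds ``active_threshold``.
    """

    n_guides: int = 20
    sites_per_guide: int = 500
    max_mismatches: int = 6
    prevalence_active: float = 0.03
    beta0: float = 6.0
    beta_mm: float = 1.2
    seed_region: tuple[int, int] = (13, 20)
    seed_penalty_multiplier: float = 2.0
    dispersion: float = 2.0
    active_threshold: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_active < 1.0:
            raise ValueError("prevalence_active must lie in (0, 1)")
        if self.max_mismatches > PROTOSPACER_LEN:
            raise ValueError("max_mismatches exceeds the protospacer length")


@dataclasses.dataclass
class BESimParams:
    """Base-editing-screen simulation parameters.

    ``position_effects`` maps (1-based position, nucleotide) to an additive
    z contribution; the defaults are concentrated at PAM-proximal positions
    (the seed region next to the PAM at positions 21-23).
    ``motif_effects`` adds a contribution per occurrence of a 3-mer.
    After summing effects and Gaussian noise, an affine calibration pins
    the z < -2 mass at ``tail_fraction``.
    """

    n_guides: int = 5000
    position_effects: dict[tuple[int, str], float] = dataclasses.field(
        default_factory=lambda: {
            (20, "A"): -1.0,
            (17, "A"): -0.8,
            (19, "C"): -0.5,
            (18, "T"): 0.4,
            (16, "G"): 0.5,
            (15, "A"): -0.3,
            (14, "C"): 0.3,
        }
    )
    motif_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"GGC": -0.25, "AAA": 0.2}
    )
    noise_sd: float = 0.6
    tail_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        for value in self.position_effects.values():
            if not np.isfinite(value):
                raise ValueError("position effects must be finite")


def _guide_rng(seed: int, guide_index: int) -> np.random.Generator:
    # counter-based stream: guide output is invariant to n_guides
    return np.random.default_rng([seed, guide_index])


def _random_guide(rng: np.random.Generator) -> str:
    protospacer = "".join(rng.choice(DNA_BASES, size=PROTOSPACER_LEN))
    pam_n = rng.choice(DNA_BASES)
    return protospacer + pam_n + PAM


def _seed_positions(params: KOSimParams) -> set[int]:
    lo, hi = params.seed_region
    return set(range(lo, hi + 1))


def _activity_prob_by_mismatch(params: KOSimParams) -> np.ndarray:
    """Exact P(count > threshold | m mismatches) for m = 0..max_mismatches.

    Mismatch positions are uniform without replacement over the protospacer,
    so the number landing in the seed region is hypergeometric; the count is
    negative-binomial around exp(beta0 - beta_mm * burden).
    """
    n_seed = len(_seed_positions(params))
    probs = np.zeros(params.max_mismatches + 1)
    for m in range(params.max_mismatches + 1):
        p_act = 0.0
        for s in range(0, min(m, n_seed) + 1):
            w = stats.hypergeom.pmf(s, PROTOSPACER_LEN, n_seed, m)
            if w == 0.0:
                continue
            burden = (m - s) + params.seed_penalty_multiplier * s
            mean = np.exp(params.beta0 - params.beta_mm * burden)
            r = params.dispersion
            p_act += w * stats.nbinom.sf(
                params.active_threshold, r, r / (r + mean)
            )
        probs[m] = p_act
    return probs


def mismatch_count_distribution(params: KOSimParams) -> np.ndarray:
    """Probability of each mismatch count m = 0..max_mismatches.

    A two-component mixture: a low-distance component concentrated at
    m in {0, 1} (weights 0.6/0.4) and a high-distance component with weights
    proportional to exp(0.8 m) for m >= 2 (site abundance grows roughly
    exponentially with the number of allowed mismatches). The mixing
    fraction is solved so the expected active fraction at the count
    threshold equals ``prevalence_active``; an unreachable target falls back
    to the nearest endpoint with a warning.
    """
    m_max = params.max_mismatches
    low = np.zeros(m_max + 1)
    low[0] = 0.6
    low[1 if m_max >= 1 else 0] += 0.4
    high = np.zeros(m_max + 1)
    if m_max >= 2:
        ms = np.arange(2, m_max + 1)
        high[2:] = np.exp(0.8 * ms)
        high /= high.sum()
    else:
        high = low.copy()
    p_act = _activity_prob_by_mismatch(params)
    p_low = float(low @ p_act)
    p_high = float(high @ p_act)
    if abs(p_low - p_high) < 1e-12:
        q = 0.5
    else:
        q = (params.prevalence_active - p_high) / (p_low - p_high)
    q = min(max(q, 0.0), 1.0)
    achieved = q * p_low + (1.0 - q) * p_high
    target = params.prevalence_active
    if abs(achieved - target) > 0.1 * target:
        warnings.warn(
            f"target prevalence {target:.3g} not reachable at these betas; "
            f"expected active fraction ~{achieved:.3g}",
            stacklevel=2,
        )
    return q * low + (1.0 - q) * high


def simulate_ko(params: KOSimParams | None = None) -> DatasetTable:
    """Simulate a paired off-target dataset (KO task).

    Each site draws a mismatch count from
    :func:`mismatch_count_distribution`, mismatch positions uniformly over
    the protospacer (seed-region hits contribute
    ``seed_penalty_multiplier``-fold burden), substituted bases uniformly
    over the three alternatives, and a negative-binomial read count with
    mean exp(beta0 - beta_mm * burden). Deterministic given ``params.seed``.
    """
    params = params or KOSimParams()
    m_dist = mismatch_count_distribution(params)
    seed_pos = _seed_positions(params)
    records: list[PairedSiteRecord] = []
    for gi in range(params.n_guides):
        rng = _guide_rng(params.seed, gi)
        guide = _random_guide(rng)
        guide_id = f"guide{gi:03d}"
        for si in range(params.sites_per_guide):
            m = int(rng.choice(len(m_dist), p=m_dist))
            positions = rng.choice(PROTOSPACER_LEN, size=m, replace=False) + 1
            target = list(guide)
            burden = 0.0
            for pos in positions:
                alternatives = [b for b in DNA_BASES if b != guide[pos - 1]]
                target[pos - 1] = alternatives[rng.integers(3)]
                burden += (
                    params.seed_penalty_multiplier if pos in seed_pos else 1.0
                )
            mean = np.exp(params.beta0 - params.beta_mm * burden)
            r = params.dispersion
            count = int(rng.negative_binomial(r, r / (r + mean)))
            records.append(
                PairedSiteRecord(
                    guide_id=guide_id,
                    guide_seq=guide,
                    target_seq="".join(target),
                    read_count=float(count),
                )
            )
    achieved = float(
        np.mean([rec.read_count > params.active_threshold for rec in records])
    )
    return DatasetTable(
        "KO",
        records,
        provenance={
            "generator": "simulate_ko",
            "params": dataclasses.asdict(params),
            "achieved_prevalence": achieved,
        },
    )


def simulate_be(params: BESimParams | None = None) -> DatasetTable:
    """Simulate a base-editing screen (BE task).

    z_i = sum of position effects + sum of motif effects + N(0, noise_sd),
    affinely calibrated (standardize, then shift) so that the empirical
    ``tail_fraction`` quantile sits at -2. Deterministic given
    ``params.seed``.
    """
    params = params or BESimParams()
    guides: list[tuple[str, str]] = []
    raw = np.empty(params.n_guides)
    for gi in range(params.n_guides):
        rng = _guide_rng(params.seed, gi)
        seq = _random_guide(rng)
        z = 0.0
        for (pos, base), effect in params.position_effects.items():
            if seq[pos - 1] == base:
                z += effect
        for motif, effect in params.motif_effects.items():
            k = len(motif)
            z += effect * sum(
                seq[i : i + k] == motif for i in range(len(seq) - k + 1)
            )
        z += rng.normal(0.0, params.noise_sd)
        guides.append((f"guide{gi:05d}", seq))
        raw[gi] = z
    sd = float(raw.std())
    if sd < 1e-9:
        raise DegenerateVarianceError(
            "simulated z-scores are (near-)constant; add effects or noise"
        )
    z_std = (raw - raw.mean()) / sd
    shift = float(np.quantile(z_std, params.tail_fraction)) + 2.0
    z_cal = z_std - shift
    records = [
        BEScreenRecord(guide_id=gid, guide_seq=seq, zscore=float(z))
        for (gid, seq), z in zip(guides, z_cal)
    ]
    return DatasetTable(
        "BE",
        records,
        provenance={
            "generator": "simulate_be",
            "params": {
                **dataclasses.asdict(params),
                "position_effects": {
                    f"{p}{b}": v for (p, b), v in params.position_effects.items()
                },
            },
            "achieved_tail_fraction": float(np.mean(z_cal < -2.0)),
        },
    )


def inject_bulges(
    table: DatasetTable, fraction: float, seed: int = 0
) -> DatasetTable:
    """Insert one gap column into a random ``fraction`` of KO pairs.

    Guide-gap and target-gap columns are equiprobable; the facing sequence
    receives a random base, so no column ever pairs gap with gap.
    """
    if table.task != "KO":
        raise ValueError("bulge injection applies to KO tables")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 2**20])
    n = len(table.records)
    n_inject = int(round(fraction * n))
    chosen = set(rng.choice(n, size=n_inject, replace=False)) if n_inject else set()
    records = []
    for i, rec in enumerate(table.records):
        if i not in chosen:
            records.append(rec)
            continue
        length = len(rec.guide_seq)
        col = int(rng.integers(length + 1))
        base = DNA_BASES[rng.integers(4)]
        if rng.integers(2) == 0:  # gap in the guide
            guide = rec.guide_seq[:col] + GAP + rec.guide_seq[col:]
            target = rec.target_seq[:col] + base + rec.target_seq[col:]
        else:  # gap in the target
            guide = rec.guide_seq[:col] + base + rec.guide_seq[col:]
            target = rec.target_seq[:col] + GAP + rec.target_seq[col:]
        records.append(dataclasses.replace(rec, guide_seq=guide, target_seq=target))
    out = table.replace_records(records)
    out.provenance["bulge_fraction"] = fraction
    return out
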