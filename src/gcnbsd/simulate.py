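"""Synthetic ADHD-biotype cohorts with planted structure.

The generator emulates the study design the package targets: a discovery
cohort of controls plus two patient biotypes whose FNC differs from the
shared baseline connectivity by biotype-specific network-block shifts, with
site offsets and independent edge noise; age/gender phenotypes; correlated
cognitive scores; and longitudinal symptom trajectories under two
medication arms, where biotype 2's improvement plateaus after week 4.

Default group sizes (116 HC / 82 biotype 1 / 25 biotype 2) mirror the
discovery cohort proportions at one tenth scale.  Everything is
reproducible from the config seed; truth labels are returned separately
from any analysis output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fnc import NetworkAtlas, default_atlas, block_edge_indices, n_edges

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort",
           "generate_cohort_pair", "default_effect_patterns",
           "LONGITUDINAL_SCALES", "COGNITION_SCALES"]

COGNITION_SCALES = ("PVT", "FICA", "LSWMT", "DCCST", "PCPST", "PSMT",
                    "ORRT", "Fluid", "Crystallized", "Total")
LONGITUDINAL_SCALES = ("RS_IN", "RS_HI", "RS_Total",
                       "CPRS_IH", "CPRS_LP", "CPRS_HIndex")

# Baseline symptom severity per biotype: biotype 2 presents more severe
# hyperactive/impulsive and total symptoms.
_BASELINES = {
    1: {"RS_IN": 22.0, "RS_HI": 19.0, "RS_Total": 45.0,
        "CPRS_IH": 5.0, "CPRS_LP": 6.0, "CPRS_HIndex": 13.0},
    2: {"RS_IN": 24.0, "RS_HI": 22.0, "RS_Total": 49.0,
        "CPRS_IH": 6.3, "CPRS_LP": 7.0, "CPRS_HIndex": 15.0},
}


def default_effect_patterns(scale: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Default 7x7 network-block FNC shifts for the two planted biotypes.

    Signs follow the qualitative connectivity profiles the biotypes are
    meant to exhibit: biotype 1 with hyperconnectivity within DM and among
    SM/CC/CB and VI/SM, hypoconnectivity SM-DM and VI-CB; biotype 2 with
    the reverse pattern on the shared blocks plus AU involvement.
    """
    # network order: SC=0, AU=1, SM=2, VI=3, CC=4, DM=5, CB=6
    b1 = np.zeros((7, 7))
    b2 = np.zeros((7, 7))

    def put(m, i, j, v):
        m[i, j] = m[j, i] = v

    put(b1, 5, 5, +1); put(b1, 2, 4, +1); put(b1, 4, 6, +1)
    put(b1, 3, 2, +1); put(b1, 3, 0, +1)
    put(b1, 2, 5, -1); put(b1, 3, 6, -1)

    put(b2, 2, 5, +1); put(b2, 3, 6, +1); put(b2, 1, 4, +1); put(b2, 1, 5, +1)
    put(b2, 3, 2, -1); put(b2, 6, 5, -1); put(b2, 5, 5, -1); put(b2, 4, 6, -1)
    return b1 * scale, b2 * scale


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohorts (all units documented).

    ``effect_b1/effect_b2`` are symmetric 7x7 network-block mean FNC shifts
    in correlation units; ``None`` uses :func:`default_effect_patterns`
    scaled by ``effect_scale``.  ``cognition_loading`` is the biotype-1 vs.
    biotype-2 gap in cognitive score points (SD ``cognition_sd``), and
    ``response_rate`` maps (biotype, arm) to the asymptotic proportional
    symptom reduction; biotype 2's reduction is frozen after
    ``plateau_week``.
    """

    n_hc: int = 116
    n_biotype1: int = 82
    n_biotype2: int = 25
    effect_scale: float = 0.3
    effect_b1: np.ndarray | None = None
    effect_b2: np.ndarray | None = None
    noise_sd: float = 0.1
    n_sites: int = 2
    site_sd: float = 0.05
    age_range_months: tuple[int, int] = (108, 132)
    male_proportion: float = 0.65
    cognition_hc_mean: float = 100.0
    cognition_hc_gap: float = 4.0       # HC minus biotype 1, score points
    cognition_loading: float = 6.0      # biotype 1 minus biotype 2
    cognition_sd: float = 15.0
    treated_fraction: float = 1.0
    mph_proportion: float = 0.6
    response_rate: dict = field(default_factory=lambda: {
        (1, "MPH"): 0.55, (1, "ATX"): 0.45,
        (2, "MPH"): 0.40, (2, "ATX"): 0.28})
    response_tau_weeks: float = 2.5
    plateau_week: int | None = 4        # applies to biotype 2
    baseline_jitter_sd: float = 2.0
    score_noise_sd: float = 1.5
    seed: int = 0
    atlas: NetworkAtlas | None = None

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_biotype1, self.n_biotype2) < 2:
            raise ValueError("all group sizes must be >= 2")
        if self.noise_sd < 0 or self.site_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        for m in (self.effect_b1, self.effect_b2):
            if m is not None:
                m = np.asarray(m, float)
                if m.shape != (7, 7) or not np.allclose(m, m.T):
                    raise ValueError("effect matrices must be symmetric 7x7")
        b1, b2 = self._effects()
        if max(np.abs(b1).max(), np.abs(b2).max()) > 0.9:
            raise ValueError("block shifts above 0.9 cannot fit in [-0.99, 0.99]")

    def _effects(self) -> tuple[np.ndarray, np.ndarray]:
        d1, d2 = default_effect_patterns(self.effect_scale)
        b1 = d1 if self.effect_b1 is None else np.asarray(self.effect_b1, float)
        b2 = d2 if self.effect_b2 is None else np.asarray(self.effect_b2, float)
        return b1, b2


@dataclass
class SyntheticCohort:
    """A generated cohort: features, phenotypes, scores and planted truth."""

    subject_ids: list[str]
    fnc: np.ndarray                 # N x 1378, correlation scale
    phenotypes: pd.DataFrame        # subject_id, diagnosis, age_months, gender,
                                    # site, scanner, medication
    true_labels: np.ndarray         # 0 = HC, 1/2 = planted biotype
    cognition: pd.DataFrame         # subject_id + one column per scale
    longitudinal: pd.DataFrame      # subject_id, scale, week, score
    atlas: NetworkAtlas

    @property
    def patient_index(self) -> np.ndarray:
        return np.flatnonzero(self.true_labels > 0)

    @property
    def diagnosis(self) -> np.ndarray:
        return (self.true_labels > 0).astype(int)


def _block_shift_vector(effect: np.ndarray, atlas: NetworkAtlas) -> np.ndarray:
    shift = np.zeros(n_edges(atlas.n_components))
    for (i, j), idx in block_edge_indices(atlas).items():
        shift[idx] = effect[i, j]
    return shift


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort from the planted-biotype generative model."""
    rng = np.random.default_rng(cfg.seed)
    atlas = cfg.atlas or default_atlas()
    e = n_edges(atlas.n_components)
    b1, b2 = cfg._effects()
    shifts = {0: np.zeros(e),
              1: _block_shift_vector(b1, atlas),
              2: _block_shift_vector(b2, atlas)}

    baseline_edges = rng.normal(0.10, 0.12, size=e)
    site_offsets = rng.normal(0.0, cfg.site_sd, size=(cfg.n_sites, e))

    groups = [0] * cfg.n_hc + [1] * cfg.n_biotype1 + [2] * cfg.n_biotype2
    n = len(groups)
    labels = np.array(groups)
    ids = [f"sub_{i:04d}" for i in range(n)]

    ages = rng.integers(cfg.age_range_months[0], cfg.age_range_months[1] + 1,
                        size=n).astype(float)
    genders = np.where(rng.random(n) < cfg.male_proportion, "M", "F")
    sites = rng.integers(cfg.n_sites, size=n)

    fnc = np.empty((n, e))
    for i, grp in enumerate(labels):
        vals = (baseline_edges + shifts[grp] + site_offsets[sites[i]]
                + rng.normal(0.0, cfg.noise_sd, size=e))
        fnc[i] = np.clip(vals, -0.99, 0.99)

    # cognition: HC highest, biotype 1 intermediate, biotype 2 lowest
    means = {0: cfg.cognition_hc_mean,
             1: cfg.cognition_hc_mean - cfg.cognition_hc_gap,
             2: cfg.cognition_hc_mean - cfg.cognition_hc_gap - cfg.cognition_loading}
    cog = {"subject_id": ids}
    for scale in COGNITION_SCALES:
        cog[scale] = np.array([means[g] for g in labels]) \
            + rng.normal(0.0, cfg.cognition_sd, size=n)
    cognition = pd.DataFrame(cog)

    # medication arms and longitudinal trajectories for treated patients
    medication = np.array(["none"] * n, dtype=object)
    long_rows: list[tuple] = []
    for i, grp in enumerate(labels):
        if grp == 0:
            continue
        if rng.random() >= cfg.treated_fraction:
            continue
        arm = "MPH" if rng.random() < cfg.mph_proportion else "ATX"
        medication[i] = arm
        r_max = cfg.response_rate[(int(grp), arm)]
        for scale in LONGITUDINAL_SCALES:
            base = max(1.0, _BASELINES[int(grp)][scale]
                       + rng.normal(0.0, cfg.baseline_jitter_sd))
            long_rows.append((ids[i], scale, 0, base))
            for week in (1, 2, 3, 4, 8):
                w_eff = week
                if grp == 2 and cfg.plateau_week is not None:
                    w_eff = min(week, cfg.plateau_week)
                red = r_max * (1.0 - np.exp(-w_eff / cfg.response_tau_weeks))
                score = base * (1.0 - red) + rng.normal(0.0, cfg.score_noise_sd)
                long_rows.append((ids[i], scale, week, max(0.0, score)))
    longitudinal = pd.DataFrame(
        long_rows, columns=["subject_id", "scale", "week", "score"])

    phenotypes = pd.DataFrame({
        "subject_id": ids,
        "diagnosis": (labels > 0).astype(int),
        "age_months": ages,
        "gender": genders,
        "site": [f"site_{s}" for s in sites],
        "scanner": [f"scanner_{s}" for s in sites],
        "medication": medication,
    })
    return SyntheticCohort(subject_ids=ids, fnc=fnc, phenotypes=phenotypes,
                           true_labels=labels, cognition=cognition,
                           longitudinal=longitudinal, atlas=atlas)


def generate_cohort_pair(cfg: GeneratorConfig, validation_overrides:
                         dict | None = None
                         ) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Discovery/validation cohort pair sharing the planted effect pattern.

    The validation cohort redraws baseline connectivity, subjects and noise
    from a seed derived from the discovery seed; overrides may change group
    sizes, sites or noise but the block-shift pattern is shared unless
    overridden explicitly.
    """
    discovery = generate_cohort(cfg)
    overrides = dict(validation_overrides or {})
    overrides.setdefault("seed", int((cfg.seed * 2654435761 + 97) % (2 ** 31)))
    validation_cfg = replace(cfg, **overrides)
    return discovery, generate_cohort(validation_cfg)
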