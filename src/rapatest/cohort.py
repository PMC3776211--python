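"""Synthetic cohorts, raw assay data and expression matrices.

The study's patient lymphocyte cultures and brain arrays are not deposited
anywhere, so this module generates data with the statistical structure the
analysis assumes: a blunted rapamycin-induced lengthening of doubling time
and G1 time in AD relative to Control lymphocytes, a rapamycin response
independent of ApoE4 carrier status, LDH triplicates with CV < 10%, and a
1165-gene rapamycin-regulated panel whose differential-expression structure
is tiered by disease stage (shared early/late signatures plus stage-specific
ones).  Ground truth is recorded next to every raw synthetic measurement so
each downstream stage can be tested by round trip.

Between-subject variation on kinetic quantities is log-normal (they are
positive and noise is multiplicative).  MCI subjects are a 50/50 mixture of
control-like and AD-like response distributions.  A single global seed
hierarchically derives independent per-subject streams, so any subject's
data is reproducible regardless of cohort order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcycle import DNAHistogram
from .ldh import Condition

__all__ = [
    "Subject", "SubjectAssay", "Cohort",
    "SyntheticCohortSpec", "SyntheticExpressionSpec",
    "generate_cohort", "generate_histogram", "generate_expression",
    "PAPER_PRESET", "EXPRESSION_PRESET",
]

DIAGNOSES = ("Control", "MCI", "AD")
EXPRESSION_GROUPS = ("Control", "Limbic", "Neocortical")

#: Default G1-peak position on the DNA-content axis (channel units).
G1_CHANNEL = 200.0
#: Default channel grid: 256 bins spanning [0, 600].
N_CHANNELS = 256
CHANNEL_MAX = 600.0

# LDH plate constants used by the generator (calibration-line truth).
LDH_SLOPE = 1.0e-5        # absorbance per cell
LDH_INTERCEPT = 0.05      # background absorbance
SEED_CELLS = 1.0e5        # cells per well at seeding
CULTURE_HOURS = 72.0
STANDARD_CELLS = (0.0, 5e4, 1e5, 1.5e5, 2e5, 2.5e5)


@dataclass(frozen=True)
class Subject:
    id: str
    age: int
    diagnosis: str
    apoe4: bool

    def __post_init__(self) -> None:
        if not (50 <= self.age <= 100):
            raise ValueError(f"age {self.age} outside [50, 100]")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


@dataclass
class SyntheticCohortSpec:
    """All generator knobs for the lymphocyte arm (defaults = study preset)."""

    n_control: int = 68
    n_mci: int = 27
    n_ad: int = 51
    seed: int = 0
    mean_pdt_baseline: float = 30.0          # hours
    pdt_ratio_control: float = 1.6           # treated/untreated, >1 = lengthening
    pdt_ratio_ad: float = 1.15
    g1_ratio_control: float = 1.9
    g1_ratio_ad: float = 1.25
    between_subject_cv: float = 0.15
    triplicate_cv: float = 0.05
    apoe4_prevalence_by_group: dict = field(
        default_factory=lambda: {"Control": 0.25, "MCI": 0.40, "AD": 0.50})
    histogram_events: int = 20000
    histogram_cv: float = 0.04               # G1 peak width / mode
    mci_ad_like_fraction: float = 0.5
    age_low: int = 57
    age_high: int = 95
    untreated_fractions: tuple = (0.04, 0.55, 0.25, 0.16)  # sub-G1, G0/G1, S, G2/M
    apoptotic_shift: float = 0.01

    def __post_init__(self) -> None:
        for name in ("between_subject_cv", "triplicate_cv", "histogram_cv"):
            v = getattr(self, name)
            if not (0 <= v < 0.5):
                raise ValueError(f"{name}={v} outside [0, 0.5)")
        if self.histogram_cv <= 0:
            raise ValueError("histogram_cv must be positive")
        if not (self.pdt_ratio_control > self.pdt_ratio_ad >= 1):
            raise ValueError("default preset requires pdt_ratio_control > pdt_ratio_ad >= 1")
        if min(self.n_control, self.n_mci, self.n_ad) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_control + self.n_mci + self.n_ad == 0:
            raise ValueError("cohort is empty: zero subjects in every group")
        if abs(sum(self.untreated_fractions) - 1.0) > 1e-9:
            raise ValueError("untreated_fractions must sum to 1")


@dataclass
class SubjectAssay:
    """Raw synthetic measurements plus recorded ground truth for one subject."""

    subject: Subject
    standards: list            # (cells, absorbance) calibration points
    plate: dict                # Condition -> list of replicate absorbances
    hist_untreated: DNAHistogram
    hist_treated: DNAHistogram
    truth: dict                # pdt_baseline, pdt_ratio, g1_ratio, fractions...


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    subjects: list
    assays: dict               # subject id -> SubjectAssay

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": s.id, "age": s.age, "diagnosis": s.diagnosis,
              "apoe4": s.apoe4} for s in self.subjects])

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            t = self.assays[s.id].truth
            rows.append({"id": s.id, "diagnosis": s.diagnosis, "apoe4": s.apoe4,
                         "pdt_baseline": t["pdt_baseline"],
                         "pdt_ratio": t["pdt_ratio"], "g1_ratio": t["g1_ratio"]})
        return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw with the requested arithmetic mean and coefficient of variation."""
    if cv == 0:
        return mean
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2)))


def generate_histogram(fractions, n_events: int, cv: float, seed,
                       g1_channel: float = G1_CHANNEL,
                       n_channels: int = N_CHANNELS,
                       channel_max: float = CHANNEL_MAX) -> DNAHistogram:
    """Draw a DNA-content histogram from the deconvolution model itself.

    ``fractions`` is (sub_g1, g0g1, s, g2m), non-negative and summing to 1.
    G1 events are N(mu, cv*mu); G2/M events N(2mu, 2*cv*mu); S events are a
    broadened rectangle (uniform on [mu, 2mu] plus N(0, cv*mu)); sub-G1
    events sit well below the G1 gate at N(0.55*mu, cv*mu).  Using the same
    parametric family as the fit closes the generate-refit test loop.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.size != 4 or np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 4 non-negative values summing to 1")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, frac)
    sigma = cv * g1_channel
    events = []
    if counts[0]:
        events.append(rng.normal(0.55 * g1_channel, sigma, counts[0]))
    if counts[1]:
        events.append(rng.normal(g1_channel, sigma, counts[1]))
    if counts[2]:
        events.append(rng.uniform(g1_channel, 2 * g1_channel, counts[2])
                      + rng.normal(0.0, sigma, counts[2]))
    if counts[3]:
        events.append(rng.normal(2 * g1_channel, 2 * sigma, counts[3]))
    ev = np.concatenate(events)
    edges = np.linspace(0.0, channel_max, n_channels + 1)
    hist, _ = np.histogram(np.clip(ev, 0.0, channel_max - 1e-9), bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return DNAHistogram(channel_midpoints=mids, counts=hist.astype(float))


def _treated_fractions(untreated: np.ndarray, pdt_ratio: float, g1_ratio: float,
                       apoptotic_shift: float) -> tuple[np.ndarray, float]:
    """Phase fractions after treatment, given the subject's response ratios.

    G1 time = PDT x G0/G1 occupancy (among cycling cells), so the treated
    occupancy is the untreated one scaled by g1_ratio/pdt_ratio; S and G2/M
    share the remaining cycling mass proportionally.  Occupancy is clipped to
    0.95 and the realized (possibly smaller) g1_ratio is returned as truth.
    """
    sub, g1, s, g2 = untreated
    cycling = g1 + s + g2
    occ_u = g1 / cycling
    occ_t = occ_u * g1_ratio / pdt_ratio
    if occ_t > 0.95:
        occ_t = 0.95
    realized_g1_ratio = pdt_ratio * occ_t / occ_u
    sub_t = min(sub + apoptotic_shift, 0.5)
    cycling_t = 1.0 - sub_t
    rest = 1.0 - occ_t
    s_share = s / (s + g2)
    out = np.array([sub_t, cycling_t * occ_t,
                    cycling_t * rest * s_share, cycling_t * rest * (1 - s_share)])
    return out, realized_g1_ratio


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate subjects with LDH plates and PI histograms for both cultures."""
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_control + spec.n_mci + spec.n_ad
    streams = root.spawn(n_total)

    labels = (["Control"] * spec.n_control + ["MCI"] * spec.n_mci
              + ["AD"] * spec.n_ad)
    subjects, assays = [], {}
    standards = [(c, LDH_SLOPE * c + LDH_INTERCEPT) for c in STANDARD_CELLS]

    for i, (dx, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        sid = f"S{i:04d}"
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
        apoe4 = bool(rng.random() < spec.apoe4_prevalence_by_group[dx])

        # Response distribution: drawn independently of the ApoE4 flag.
        if dx == "AD" or (dx == "MCI" and rng.random() < spec.mci_ad_like_fraction):
            pdt_target, g1_target = spec.pdt_ratio_ad, spec.g1_ratio_ad
        else:
            pdt_target, g1_target = spec.pdt_ratio_control, spec.g1_ratio_control

        pdt_u = _lognormal(rng, spec.mean_pdt_baseline, spec.between_subject_cv)
        # log-normal draws keep ratios positive and their arm means on target
        pdt_ratio = _lognormal(rng, pdt_target, spec.between_subject_cv)
        g1_ratio = _lognormal(rng, g1_target, spec.between_subject_cv)
        pdt_t = pdt_u * pdt_ratio

        frac_u = np.asarray(spec.untreated_fractions, dtype=float)
        frac_t, g1_ratio = _treated_fractions(frac_u, pdt_ratio, g1_ratio,
                                              spec.apoptotic_shift)

        n_end_u = SEED_CELLS * 2.0 ** (CULTURE_HOURS / pdt_u)
        n_end_t = SEED_CELLS * 2.0 ** (CULTURE_HOURS / pdt_t)

        def triplicate(cells: float) -> list[float]:
            a = LDH_SLOPE * cells + LDH_INTERCEPT
            if spec.triplicate_cv == 0:
                return [a, a, a]
            return list(a * rng.normal(1.0, spec.triplicate_cv, 3).clip(min=0.0))

        plate = {
            Condition.SEED: triplicate(SEED_CELLS),
            Condition.UNTREATED_72H: triplicate(n_end_u),
            Condition.RAPAMYCIN_72H: triplicate(n_end_t),
        }
        h_seed_u, h_seed_t = ss.spawn(2)
        hist_u = generate_histogram(frac_u, spec.histogram_events,
                                    spec.histogram_cv, h_seed_u)
        hist_t = generate_histogram(frac_t, spec.histogram_events,
                                    spec.histogram_cv, h_seed_t)

        subj = Subject(id=sid, age=age, diagnosis=dx, apoe4=apoe4)
        subjects.append(subj)
        assays[sid] = SubjectAssay(
            subject=subj, standards=standards, plate=plate,
            hist_untreated=hist_u, hist_treated=hist_t,
            truth={"pdt_baseline": pdt_u, "pdt_ratio": pdt_ratio,
                   "g1_ratio": g1_ratio, "n_end_untreated": n_end_u,
                   "n_end_treated": n_end_t,
                   "fractions_untreated": tuple(frac_u),
                   "fractions_treated": tuple(frac_t)})
    return Cohort(spec=spec, subjects=subjects, assays=assays)


@dataclass
class SyntheticExpressionSpec:
    """Generator knobs for the brain expression arm (defaults = study preset:
    5 controls, 19 limbic-stage and 22 neocortical-stage samples over a
    1165-gene panel with a 33/22/17/81 signature tier structure)."""

    n_control: int = 5
    n_limbic: int = 19
    n_neocortical: int = 22
    n_panel: int = 1165
    signature_shared_up: int = 33
    signature_shared_down: int = 22
    signature_limbic_only: int = 17
    signature_neocortical_only: int = 81
    effect_size_log2: float = 1.5
    gene_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n_sig = (self.signature_shared_up + self.signature_shared_down
                 + self.signature_limbic_only + self.signature_neocortical_only)
        if n_sig > self.n_panel:
            raise ValueError(f"signature genes ({n_sig}) exceed panel size "
                             f"({self.n_panel})")
        if min(self.n_control, self.n_limbic, self.n_neocortical) < 2:
            raise ValueError("every sample group needs >= 2 samples")


def generate_expression(spec: SyntheticExpressionSpec
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (log2 expression matrix, sample-group table, truth sets).

    Non-signature genes share one mean across groups; signature genes are
    shifted by ``effect_size_log2`` in the stated disease-stage groups
    (shared-up/down in both stages, stage-specific up in one stage only).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    genes = [f"RRG{i + 1:04d}" for i in range(spec.n_panel)]
    sample_ids, groups = [], []
    for grp, n in zip(EXPRESSION_GROUPS,
                      (spec.n_control, spec.n_limbic, spec.n_neocortical)):
        for j in range(n):
            sample_ids.append(f"{grp[0]}{j + 1:02d}")
            groups.append(grp)
    groups = np.array(groups)

    base = rng.uniform(6.0, 12.0, spec.n_panel)
    mat = base[:, None] + rng.normal(0.0, spec.gene_noise_sd,
                                     (spec.n_panel, len(sample_ids)))

    idx = 0
    truth = {}
    for name, count, sign, stages in (
            ("shared_up", spec.signature_shared_up, +1, ("Limbic", "Neocortical")),
            ("shared_down", spec.signature_shared_down, -1, ("Limbic", "Neocortical")),
            ("limbic_only", spec.signature_limbic_only, +1, ("Limbic",)),
            ("neocortical_only", spec.signature_neocortical_only, +1, ("Neocortical",))):
        sel = slice(idx, idx + count)
        col_mask = np.isin(groups, stages)
        mat[sel, :] += sign * spec.effect_size_log2 * col_mask[None, :]
        truth[name] = genes[idx:idx + count]
        idx += count

    matrix = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    group_table = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return matrix, group_table, truth


#: Ready-made study presets.
PAPER_PRESET = SyntheticCohortSpec()
EXPRESSION_PRESET = SyntheticExpressionSpec()
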