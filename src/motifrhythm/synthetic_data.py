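"""Synthetic nest generator.

Emulates the structure of a zebra-finch tutor-tutee recording study so the
whole pipeline is testable without real recordings: nests of one tutor and
1-4 tutees, ten crystallised motifs per bird, element onsets governed by a
per-bird quasi-isochronous beat with a bimodal interval structure (short
gaps between elements within a syllable, longer gaps between syllables),
and tutee songs that fully copy, partially copy, or improvise on the
tutor's element sequence.

Timing model per bird: a fixed base interval pattern (unit weight for
intra-syllable gaps, ``ioi_ratio_inter_intra`` for inter-syllable gaps) is
scaled so its mean equals 1/beat, then each interval receives independent
multiplicative log-normal jitter.  The jitter magnitude is solved from
``ioi_jitter_cv``, the target *total* within-motif CV, after accounting for
the spread the bimodal base pattern already contributes; a target below the
base-pattern CV is infeasible and raises a validation error.

Tutee beats are derived from their tutor's beat (divided by
``tutee_slowdown_factor``, with small log-normal noise), so nest-level
tutor-tutee beat correlation is an emergent, controllable property.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_annotations import write_csv, write_textgrid
from .records import AnnotatedMotif, Element

STRATEGIES = ("full_copy", "partial_copy", "improvise")


@dataclass
class GeneratorConfig:
    """Study-shaped defaults; every field is overridable.

    The tutee count distribution (median 2, mean 2.15) reproduces the
    study shape of 17 nests housing ~37 tutees.  ``ioi_jitter_cv`` is the
    target total within-motif CV of intervals (0.57, the mean within-
    sequence CV reported for real song).
    """

    n_nests: int = 17
    tutees_per_nest_probs: tuple[float, ...] = (0.25, 0.45, 0.20, 0.10)  # P(1..4)
    motifs_per_bird: int = 10
    tutor_beat_mean_hz: float = 17.1
    tutor_beat_sd_hz: float = 3.7
    tutor_beat_range_hz: tuple[float, float] = (8.6, 26.4)
    n_elements_min: int = 6
    n_elements_max: int = 14
    ioi_ratio_inter_intra: float = 2.5
    ioi_support_s: tuple[float, float] = (0.009, 0.29)
    intra_ioi_s: Optional[float] = 0.04  # None -> proportional-to-tempo mode
    ioi_jitter_cv: float = 0.57
    intra_jitter_scale: float = 0.35  # intra-syllable gaps are more stereotyped
    min_ioi_jitter_cv: float = 0.08  # motor noise floor: no interval is exact
    tutee_slowdown_factor: float = 1.05
    tutee_beat_noise_cv: float = 0.015
    novel_jitter_multiplier: float = 2.0
    copy_strategy_probs: dict = field(
        default_factory=lambda: {"full_copy": 0.4, "partial_copy": 0.4, "improvise": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.tutees_per_nest_probs) - 1.0) > 1e-9:
            raise ValidationError("tutees_per_nest_probs must sum to 1")
        if abs(sum(self.copy_strategy_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("copy_strategy_probs must sum to 1")
        if set(self.copy_strategy_probs) - set(STRATEGIES):
            raise ValidationError(f"strategies must be among {STRATEGIES}")
        if self.ioi_jitter_cv < 0:
            raise ValidationError("ioi_jitter_cv must be >= 0")
        if self.tutee_slowdown_factor < 1.0:
            raise ValidationError("tutee_slowdown_factor must be >= 1")
        if self.n_elements_min < 2 or self.n_elements_max < self.n_elements_min:
            raise ValidationError("bad element-count range")
        lo, hi = self.ioi_support_s
        if not (0 < lo < hi):
            raise ValidationError("bad IOI support")


# ---------------------------------------------------------------- internals


def _interval_intra_mask(n_elements: int, rng: np.random.Generator) -> np.ndarray:
    """Random 1-3-element syllable grouping, expressed as a boolean mask
    over the n-1 intervals: True where both flanking elements share a
    syllable (an intra-syllable gap)."""
    sizes: list[int] = []
    remaining = n_elements
    while remaining > 0:
        s = int(rng.integers(1, 4))
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    mask: list[bool] = []
    for syl_i, size in enumerate(sizes):
        mask.extend([True] * (size - 1))
        if syl_i < len(sizes) - 1:
            mask.append(False)
    return np.asarray(mask, dtype=bool)


def _base_pattern(
    n_elements: int,
    mean_ioi_s: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Base interval values (mean exactly ``mean_ioi_s``) and intra mask.

    Two component models: with ``intra_ioi_s`` set (default), intra-syllable
    gaps are a species-typical constant and the inter-syllable gap absorbs
    the bird's tempo, which keeps the pooled intra mode sharp across birds;
    with ``intra_ioi_s=None`` the two components are proportional to tempo
    at ``ioi_ratio_inter_intra``.  Groupings whose solved inter gap would
    leave the support are re-drawn; an all-boundary grouping (every element
    its own syllable) is always feasible.
    """
    hi = config.ioi_support_s[1]
    if config.intra_ioi_s is None:
        mask = _interval_intra_mask(n_elements, rng)
        w = np.where(mask, 1.0, config.ioi_ratio_inter_intra)
        return w * mean_ioi_s / w.mean(), mask

    a = min(config.intra_ioi_s, 0.6 * mean_ioi_s)
    m = n_elements - 1
    for _ in range(50):
        mask = _interval_intra_mask(n_elements, rng)
        n_intra = int(mask.sum())
        n_inter = m - n_intra
        if n_inter == 0:
            continue
        x = (m * mean_ioi_s - n_intra * a) / n_inter
        if a < x <= 0.95 * hi:
            return np.where(mask, a, x), mask
    # fallback: no intra gaps at all -> every interval is a syllable boundary
    mask = np.zeros(m, dtype=bool)
    return np.full(m, mean_ioi_s), mask


def _jitter_profile(
    weights: np.ndarray,
    jitter_scales: np.ndarray,
    target_cv: float,
    strict: bool = True,
) -> np.ndarray:
    """Per-interval jitter CVs hitting a total within-motif CV target.

    For intervals d_k = b_k * eps_k with E[eps_k]=1 and Var[eps_k] =
    (c * s_k)^2, the within-motif variance over positions k is
    E[d^2] - E[d]^2 = mean(b^2 (1 + c^2 s^2)) - mean(b)^2, so c solves
    c^2 = (mean(b)^2 (1 + t^2) - mean(b^2)) / mean(b^2 s^2).
    A target below the base-pattern CV leaves nothing to add: error when
    ``strict``, zero jitter otherwise.
    """
    b = np.asarray(weights, float)
    s = np.asarray(jitter_scales, float)
    num = (b.mean() ** 2) * (1.0 + target_cv**2) - (b**2).mean()
    if num < -1e-12 and strict:
        base_cv = float(b.std() / b.mean())
        raise ValidationError(
            f"jitter target CV {target_cv:.3f} below the base-pattern CV "
            f"{base_cv:.3f}: infeasible with these bimodal components"
        )
    c2 = max(0.0, num) / float((b**2 * s**2).mean())
    return float(np.sqrt(c2)) * s


def _lognormal_unit_mean(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative jitter with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError("beat distribution truncation failed (bad range?)")


@dataclass
class _BirdPlan:
    """Crystallised song of one bird: fixed labels, base pattern, tempo."""

    labels: list[str]
    weights: np.ndarray  # n_elements - 1 base interval values (any scale)
    intra_mask: np.ndarray  # True where the interval is an intra-syllable gap
    beat_hz: float
    jitter_cv_per_ioi: np.ndarray  # per-interval jitter CV (novel runs higher)

    @property
    def base_iois(self) -> np.ndarray:
        return self.weights / self.weights.mean() / self.beat_hz

    def base_cv(self) -> float:
        w = self.weights
        return float(w.std() / w.mean())


def _realise_motifs(
    plan: _BirdPlan,
    nest_id: str,
    bird_id: str,
    role: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[AnnotatedMotif]:
    lo, hi = config.ioi_support_s
    motifs = []
    for m in range(config.motifs_per_bird):
        jit = np.array(
            [_lognormal_unit_mean(cv, 1, rng)[0] for cv in plan.jitter_cv_per_ioi]
        )
        iois = np.clip(plan.base_iois * jit, lo, hi)
        onsets = np.concatenate([[0.0], np.cumsum(iois)])
        elements = [
            Element(label=lab, onset_s=float(t))
            for lab, t in zip(plan.labels, onsets)
        ]
        motifs.append(
            AnnotatedMotif(
                nest_id=nest_id, bird_id=bird_id, role=role,
                motif_id=f"m{m:02d}", elements=elements,
            ).validate()
        )
    return motifs


def _tutor_plan(config: GeneratorConfig, rng: np.random.Generator) -> _BirdPlan:
    n_el = int(rng.integers(config.n_elements_min, config.n_elements_max + 1))
    labels = [string.ascii_uppercase[i] for i in range(n_el)]
    beat = _truncated_normal(
        config.tutor_beat_mean_hz, config.tutor_beat_sd_hz,
        *config.tutor_beat_range_hz, rng,
    )
    weights, mask = _base_pattern(n_el, 1.0 / beat, config, rng)
    scales = np.where(mask, config.intra_jitter_scale, 1.0)
    # the proportional model has a hard feasibility contract; the fixed-gap
    # model lets per-bird CV float with tempo, as in real song
    strict = config.intra_ioi_s is None
    jitter = _jitter_profile(weights, scales, config.ioi_jitter_cv, strict=strict)
    floor = min(config.min_ioi_jitter_cv, config.ioi_jitter_cv)
    jitter = np.maximum(jitter, floor * scales)
    return _BirdPlan(labels=labels, weights=weights, intra_mask=mask,
                     beat_hz=beat, jitter_cv_per_ioi=jitter)


def _novel_labels(n: int, tutor_labels: Sequence[str]) -> list[str]:
    pool = [c for c in string.ascii_uppercase if c not in set(tutor_labels)]
    pool += [f"Z{i}" for i in range(max(0, n - len(pool)))]
    return pool[:n]


def _tutee_plan(
    config: GeneratorConfig,
    tutor: _BirdPlan,
    strategy: str,
    rng: np.random.Generator,
) -> _BirdPlan:
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown copy strategy {strategy!r}")
    beat = tutor.beat_hz / config.tutee_slowdown_factor
    beat *= float(_lognormal_unit_mean(config.tutee_beat_noise_cv, 1, rng)[0])
    n_tutor = len(tutor.labels)

    if strategy == "full_copy":
        labels = list(tutor.labels)
        weights = tutor.weights.copy()
        intra_mask = tutor.intra_mask.copy()
        novel_mask = np.zeros(len(weights), dtype=bool)
    else:
        if strategy == "partial_copy":
            # an incomplete beginning snippet followed by invented elements
            prefix_len = int(rng.integers(4, n_tutor)) if n_tutor > 4 else 4
            prefix_len = min(prefix_len, n_tutor - 1) or 1
            novel_len = int(rng.integers(4, 7))
        else:  # improvise: mostly novel material, any copied prefix too
            prefix_len = int(rng.integers(0, 4))  # below the analysis minimum
            novel_len = int(rng.integers(5, 10))
        labels = list(tutor.labels[:prefix_len]) + _novel_labels(novel_len, tutor.labels)
        novel_weights, novel_intra = _base_pattern(
            novel_len, float(tutor.weights.mean()), config, rng
        )
        if prefix_len == 0:
            weights = novel_weights
            intra_mask = novel_intra
        else:
            prefix_weights = tutor.weights[: prefix_len - 1]
            inter = tutor.weights[~tutor.intra_mask]
            bridge = np.array([inter.mean() if inter.size else tutor.weights.mean()])
            weights = np.concatenate([prefix_weights, bridge, novel_weights])
            intra_mask = np.concatenate(
                [tutor.intra_mask[: prefix_len - 1], [False], novel_intra]
            )
        n_el = len(labels)
        # the NOT_SHARED run's internal intervals: both flanking elements novel
        novel_mask = np.arange(n_el - 1) >= prefix_len

    # non-strict: tutor feasibility was already enforced; a motif-derived
    # base pattern may sit at or above the target, leaving no jitter to add
    scales = np.where(intra_mask, config.intra_jitter_scale, 1.0)
    per_ioi = _jitter_profile(weights, scales, config.ioi_jitter_cv, strict=False)
    floor = min(config.min_ioi_jitter_cv, config.ioi_jitter_cv)
    per_ioi = np.maximum(per_ioi, floor * scales)
    per_ioi[novel_mask] *= config.novel_jitter_multiplier
    return _BirdPlan(labels=labels, weights=weights, intra_mask=intra_mask,
                     beat_hz=beat, jitter_cv_per_ioi=per_ioi)


# ------------------------------------------------------------------- public


def generate_tutor(
    config: GeneratorConfig, nest_id: str, rng: Optional[np.random.Generator] = None
) -> tuple[list[AnnotatedMotif], dict]:
    """One tutor's crystallised motifs plus its ground-truth record."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    plan = _tutor_plan(config, rng)
    bird_id = f"{nest_id}T"
    motifs = _realise_motifs(plan, nest_id, bird_id, "tutor", config, rng)
    truth = {
        "nest_id": nest_id, "bird_id": bird_id, "role": "tutor",
        "strategy": "n/a", "true_beat_hz": plan.beat_hz,
        "n_elements": len(plan.labels),
    }
    return motifs, truth


def _plan_from_motif(motif: AnnotatedMotif, config: GeneratorConfig) -> _BirdPlan:
    """Recover a timing plan from a realised motif: its IOIs become the base
    pattern.  The motif's own variability already embodies the jitter
    target, so only any shortfall is re-added (never negative)."""
    iois = motif.iois()
    # no syllable annotation on a bare motif: infer intra gaps as those
    # shorter than 60% of the mean interval
    intra_mask = iois < 0.6 * iois.mean()
    return _BirdPlan(
        labels=motif.labels, weights=iois.copy(), intra_mask=intra_mask,
        beat_hz=float(1.0 / iois.mean()),
        jitter_cv_per_ioi=_jitter_profile(
            iois, np.ones(iois.size), config.ioi_jitter_cv, strict=False
        ),
    )


def generate_tutee(
    config: GeneratorConfig,
    tutor: "_BirdPlan | AnnotatedMotif",
    strategy: str,
    nest_id: str,
    bird_id: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AnnotatedMotif], dict]:
    """One tutee's motifs under a copy strategy, relative to its tutor
    (given either as a generator plan or as a realised tutor motif)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tutor_plan = tutor if isinstance(tutor, _BirdPlan) else _plan_from_motif(tutor, config)
    plan = _tutee_plan(config, tutor_plan, strategy, rng)
    motifs = _realise_motifs(plan, nest_id, bird_id, "tutee", config, rng)
    truth = {
        "nest_id": nest_id, "bird_id": bird_id, "role": "tutee",
        "strategy": strategy, "true_beat_hz": plan.beat_hz,
        "n_elements": len(plan.labels),
    }
    return motifs, truth


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedMotif], pd.DataFrame]:
    """A full synthetic study: motifs for every bird of every nest plus a
    ground-truth sidecar (true beats, strategies). Deterministic under
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    motifs: list[AnnotatedMotif] = []
    truths: list[dict] = []
    strategies = list(config.copy_strategy_probs)
    strat_p = np.array([config.copy_strategy_probs[s] for s in strategies])
    for i in range(config.n_nests):
        nest_id = f"N{i + 1:02d}"
        tutor_plan = _tutor_plan(config, rng)
        tutor_id = f"{nest_id}T"
        motifs.extend(_realise_motifs(tutor_plan, nest_id, tutor_id, "tutor", config, rng))
        truths.append(
            {"nest_id": nest_id, "bird_id": tutor_id, "role": "tutor",
             "strategy": "n/a", "true_beat_hz": tutor_plan.beat_hz,
             "n_elements": len(tutor_plan.labels)}
        )
        n_tutees = int(rng.choice([1, 2, 3, 4], p=config.tutees_per_nest_probs))
        for k in range(n_tutees):
            strategy = str(rng.choice(strategies, p=strat_p))
            bird_id = f"{nest_id}B{k + 1}"
            plan = _tutee_plan(config, tutor_plan, strategy, rng)
            motifs.extend(_realise_motifs(plan, nest_id, bird_id, "tutee", config, rng))
            truths.append(
                {"nest_id": nest_id, "bird_id": bird_id, "role": "tutee",
                 "strategy": strategy, "true_beat_hz": plan.beat_hz,
                 "n_elements": len(plan.labels)}
            )
    truth = pd.DataFrame(
        truths, columns=["nest_id", "bird_id", "role", "strategy",
                         "true_beat_hz", "n_elements"]
    )
    return motifs, truth


def write_corpus(
    config: GeneratorConfig,
    out_dir: str | Path,
    textgrids: bool = False,
) -> dict[str, Path]:
    """Generate a corpus and write motifs.csv + ground_truth.csv (and
    optionally one TextGrid per motif)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    motifs, truth = generate_corpus(config)
    paths = {
        "motifs": write_csv(motifs, out_dir / "motifs.csv"),
        "ground_truth": out_dir / "ground_truth.csv",
    }
    truth.to_csv(paths["ground_truth"], index=False, float_format="%.6f")
    if textgrids:
        tg_dir = out_dir / "textgrids"
        for m in motifs:
            write_textgrid([m], tg_dir)
        paths["textgrids"] = tg_dir
    return paths
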