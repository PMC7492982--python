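"""Seeded synthetic cohorts: search archives plus clinical timelines.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable without real participant data:

* two cohorts (SSD cases and healthy volunteers) whose query volumes and
  query lengths differ by multiplicative group effects;
* hospitalization calendars for the cases (1–4 admissions, gamma-distributed
  gaps, uniform stays) with elevated query rates and shifted word-category
  usage in the 28 days before each admission (the illness state);
* query timestamps from an inhomogeneous Poisson process — a per-day rate
  modulated by participant frailty and illness state, with hour-of-day
  placement by a circadian weight profile;
* query text drawn word-by-word from the closed fixture vocabulary by
  category weights, so lexicon matching is exhaustively testable.

Default effect sizes are calibrated to the observed query-volume contrasts
of the study this pipeline targets: the pre-first-admission (diagnostic)
window of a case averages 0.58× the control query count and the illness/
health period ratio is 1.74, with case query length ×0.8 during illness.
Since the diagnostic window is itself an illness period here, the baseline
case rate multiplier is 0.58/1.74 ≈ 0.333 so that both ratios hold at once.
Category shifts are ×0.5 (reduced) or ×2.0 (increased), directionally
matching the published importance tables.  Effects are NOT calibrated to
reproduce any published classifier AUC.

Everything is deterministic given ``CohortSpec.seed``; per-participant
substreams come from ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta, timezone
from importlib import resources

import numpy as np

from .archive_io import ClinicalTimeline, SearchArchive, SearchQuery
from .lexicon import Lexicon, load_dic

BASE_DATE = date(2017, 1, 1)
ILLNESS_DAYS = 28  # the pre-admission state window


class SpecError(ValueError):
    """Cohort specification violates an invariant."""


# Word-sampling weight per category, aligned to the fixture lexicon's names.
# Function-word categories dominate, as in natural query text.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "funct": 4.0, "pronoun": 1.0, "ppron": 0.5, "i": 3.0, "we": 0.5,
    "you": 1.0, "shehe": 0.5, "they": 0.5, "ipron": 2.0, "article": 6.0,
    "verb": 4.0, "auxverb": 3.0, "past": 1.5, "present": 2.0, "future": 0.5,
    "adverb": 2.0, "preps": 7.0, "conj": 3.0, "negate": 1.0, "quant": 2.0,
    "number": 0.5, "swear": 0.2, "social": 2.0, "family": 0.8, "friend": 0.6,
    "humans": 0.8, "affect": 0.5, "posemo": 2.0, "negemo": 0.8, "anx": 0.8,
    "anger": 0.8, "sad": 0.8, "cogmech": 0.5, "insight": 1.2, "cause": 0.8,
    "discrep": 0.6, "tentat": 0.8, "certain": 0.6, "inhib": 1.0, "incl": 2.0,
    "excl": 1.0, "percept": 0.5, "see": 0.8, "hear": 1.0, "feel": 0.6,
    "bio": 0.5, "body": 0.8, "health": 1.2, "sexual": 0.6, "ingest": 0.8,
    "relativ": 3.0,
}

# Hour-of-day placement weights: night trough, evening peak.
DEFAULT_CIRCADIAN = (
    1.5, 1.0, 0.7, 0.5, 0.4, 0.4, 0.6, 1.2, 2.0, 2.5, 2.8, 3.0,
    3.2, 3.0, 2.8, 2.8, 3.0, 3.3, 3.6, 4.0, 4.2, 4.0, 3.3, 2.2,
)

_DIAG_SHIFTS = {
    # trait-level reductions in the case group (directionally: "reduced
    # usage of ... in SSD")
    "relativ": 0.5, "inhib": 0.5, "quant": 0.5, "posemo": 0.5,
    "anx": 0.5, "preps": 0.7, "incl": 0.5, "insight": 0.6,
}
_RELAPSE_SHIFTS = {
    # illness-state shifts in the 28 days before an admission
    "sexual": 2.0, "hear": 2.0, "bio": 2.0, "percept": 2.0, "anger": 2.0,
    "ipron": 1.5, "health": 0.5, "sad": 0.5,
}


@dataclass
class EffectSpec:
    """Multiplicative group and illness-state effects.

    Rate/length multipliers apply to the expected daily query count and the
    expected query word count; category shifts multiply the word-sampling
    weight of the named categories.  ``ssd_*`` multipliers are the case
    group's baseline (healthy-period) effects; ``illness_*`` multipliers
    stack on top within the 28 days before each admission.
    """

    ssd_rate_multiplier: float = 0.58 / 1.74
    ssd_length_multiplier: float = 1.0
    illness_rate_multiplier: float = 1.74
    illness_length_multiplier: float = 0.8
    diagnostic_category_shift: dict[str, float] = field(
        default_factory=lambda: dict(_DIAG_SHIFTS)
    )
    relapse_category_shift: dict[str, float] = field(
        default_factory=lambda: dict(_RELAPSE_SHIFTS)
    )

    def __post_init__(self) -> None:
        mults = [
            self.ssd_rate_multiplier,
            self.ssd_length_multiplier,
            self.illness_rate_multiplier,
            self.illness_length_multiplier,
            *self.diagnostic_category_shift.values(),
            *self.relapse_category_shift.values(),
        ]
        if any(not np.isfinite(m) or m <= 0 for m in mults):
            raise SpecError("all effect multipliers must be positive and finite")

    @classmethod
    def neutral(cls) -> "EffectSpec":
        """No group or state effects: cases and controls are exchangeable."""
        return cls(1.0, 1.0, 1.0, 1.0, {}, {})


@dataclass
class CohortSpec:
    """Everything the generator needs; defaults are the study conditions."""

    n_ssd: int = 72
    n_hv: int = 128
    archive_span_days: int = 365
    hosp_count_probs: tuple[float, ...] = (0.20, 0.35, 0.30, 0.15)  # P(1..4 admissions)
    first_admission_day: tuple[int, int] = (60, 150)
    gap_days_mean: float = 120.0
    gap_days_shape: float = 3.0
    stay_days: tuple[int, int] = (7, 28)
    base_query_rate: float = 11.9  # expected queries/day for a control
    circadian_profile: tuple[float, ...] = DEFAULT_CIRCADIAN
    mean_query_words: float = 3.5
    rate_frailty_sigma: float = 0.77  # lognormal, matches heavy between-person dispersion
    length_frailty_sigma: float = 0.15
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ssd, self.n_hv) < 0 or self.n_ssd + self.n_hv == 0:
            raise SpecError("cohort sizes must be nonnegative and not both zero")
        if self.archive_span_days < ILLNESS_DAYS:
            raise SpecError("archive span must cover at least one window")
        if abs(sum(self.hosp_count_probs) - 1.0) > 1e-9 or min(self.hosp_count_probs) < 0:
            raise SpecError("hosp_count_probs must be a probability vector")
        if self.base_query_rate <= 0 or self.mean_query_words < 1:
            raise SpecError("base rate must be positive and mean words >= 1")
        cp = np.asarray(self.circadian_profile, dtype=float)
        if len(cp) != 24 or (cp < 0).any() or not cp.any() or not np.isfinite(cp).all():
            raise SpecError("circadian_profile needs 24 nonnegative, not-all-zero weights")
        if any(w < 0 or not np.isfinite(w) for w in self.category_weights.values()):
            raise SpecError("category weights must be nonnegative and finite")


def fixture_lexicon_path():
    """Path to the packaged 51-category fixture dictionary."""
    return resources.files("searchtrace.data") / "fixture51.dic"


_FIXTURE_CACHE: Lexicon | None = None


def fixture_lexicon() -> Lexicon:
    """The packaged 51-category lexicon used by the generator's vocabulary."""
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        with resources.as_file(fixture_lexicon_path()) as p:
            _FIXTURE_CACHE = load_dic(p)
    return _FIXTURE_CACHE


def _weight_vector(lexicon: Lexicon, weights: dict[str, float]) -> np.ndarray:
    unknown = set(weights) - set(lexicon.category_names)
    if unknown:
        raise SpecError(f"category weights name unknown categories: {sorted(unknown)}")
    return np.array([weights.get(c, 1.0) for c in lexicon.category_names], dtype=float)


def _shift_vector(lexicon: Lexicon, shifts: dict[str, float]) -> np.ndarray:
    unknown = set(shifts) - set(lexicon.category_names)
    if unknown:
        raise SpecError(f"category shifts name unknown categories: {sorted(unknown)}")
    return np.array([shifts.get(c, 1.0) for c in lexicon.category_names], dtype=float)


def _vocab_lists(lexicon: Lexicon) -> list[np.ndarray]:
    vocab = []
    for idx in range(lexicon.n_categories):
        words = sorted(w for w, cats in lexicon.exact.items() if idx in cats)
        if not words:
            raise SpecError(
                f"fixture lexicon category {lexicon.category_names[idx]!r} has no exact words"
            )
        vocab.append(np.array(words, dtype=object))
    return vocab


def _draw_timeline(rng: np.random.Generator, spec: CohortSpec, pid: str) -> ClinicalTimeline:
    n_hosp = int(rng.choice(len(spec.hosp_count_probs), p=spec.hosp_count_probs)) + 1
    lo, hi = spec.first_admission_day
    day = int(rng.integers(lo, hi + 1))
    hosps: list[tuple[date, date]] = []
    for _ in range(n_hosp):
        stay = int(rng.integers(spec.stay_days[0], spec.stay_days[1] + 1))
        if day + stay > spec.archive_span_days - 1:
            break
        adm = BASE_DATE + timedelta(days=day)
        hosps.append((adm, adm + timedelta(days=stay)))
        gap = max(
            1,
            int(round(rng.gamma(spec.gap_days_shape, spec.gap_days_mean / spec.gap_days_shape))),
        )
        day = day + stay + gap
    if not hosps:  # calendar must keep at least the first admission
        adm = BASE_DATE + timedelta(days=day)
        hosps = [(adm, adm + timedelta(days=spec.stay_days[0]))]
    return ClinicalTimeline(pid, "SSD", hosps)


def _illness_day_mask(timeline: ClinicalTimeline | None, span: int) -> np.ndarray:
    mask = np.zeros(span, dtype=bool)
    if timeline is not None:
        for adm, _ in timeline.hospitalizations:
            a = (adm - BASE_DATE).days
            mask[max(0, a - ILLNESS_DAYS) : a] = True
    return mask


def _generate_participant(
    rng: np.random.Generator,
    spec: CohortSpec,
    pid: str,
    group: str,
    timeline: ClinicalTimeline | None,
    lexicon: Lexicon,
    vocab: list[np.ndarray],
) -> SearchArchive:
    span = spec.archive_span_days
    eff = spec.effect
    is_ssd = group == "SSD"

    # mean-one lognormal frailties so group means track the multipliers
    rate_frailty = float(
        np.exp(rng.normal(-spec.rate_frailty_sigma**2 / 2, spec.rate_frailty_sigma))
    )
    len_frailty = float(
        np.exp(rng.normal(-spec.length_frailty_sigma**2 / 2, spec.length_frailty_sigma))
    )

    illness = _illness_day_mask(timeline, span)
    rate = np.full(span, spec.base_query_rate * rate_frailty)
    if is_ssd:
        rate *= eff.ssd_rate_multiplier
        rate[illness] *= eff.illness_rate_multiplier

    counts = rng.poisson(rate)
    n_q = int(counts.sum())
    if n_q == 0:
        return SearchArchive(pid, [])
    q_day = np.repeat(np.arange(span), counts)
    circ = np.asarray(spec.circadian_profile, dtype=float)
    hours = rng.choice(24, size=n_q, p=circ / circ.sum())
    secs = rng.integers(0, 3600, size=n_q)
    q_illness = illness[q_day]

    lam = (spec.mean_query_words - 1.0) * len_frailty
    lam_q = np.full(n_q, lam)
    if is_ssd:
        lam_q *= eff.ssd_length_multiplier
        lam_q[q_illness] *= eff.illness_length_multiplier
    lengths = 1 + rng.poisson(lam_q)
    total_tokens = int(lengths.sum())

    w_base = _weight_vector(lexicon, spec.category_weights)
    if is_ssd:
        w_trait = w_base * _shift_vector(lexicon, eff.diagnostic_category_shift)
        w_ill = w_trait * _shift_vector(lexicon, eff.relapse_category_shift)
    else:
        w_trait = w_ill = w_base

    tok_illness = np.repeat(q_illness, lengths)
    cats = np.empty(total_tokens, dtype=np.int64)
    n_ill = int(tok_illness.sum())
    if total_tokens - n_ill:
        cats[~tok_illness] = rng.choice(
            lexicon.n_categories, size=total_tokens - n_ill, p=w_trait / w_trait.sum()
        )
    if n_ill:
        cats[tok_illness] = rng.choice(
            lexicon.n_categories, size=n_ill, p=w_ill / w_ill.sum()
        )
    words = np.empty(total_tokens, dtype=object)
    for c in np.unique(cats):
        sel = cats == c
        words[sel] = vocab[c][rng.integers(0, len(vocab[c]), size=int(sel.sum()))]

    bounds = np.concatenate([[0], np.cumsum(lengths)])
    base_midnight = datetime.combine(BASE_DATE, datetime.min.time(), tzinfo=timezone.utc)
    queries = []
    for i in range(n_q):
        ts = base_midnight + timedelta(
            days=int(q_day[i]), hours=int(hours[i]), seconds=int(secs[i])
        )
        text = " ".join(words[bounds[i] : bounds[i + 1]])
        queries.append(SearchQuery(ts, text, "search"))
    return SearchArchive(pid, queries)


def generate_cohort(
    spec: CohortSpec, lexicon: Lexicon | None = None
) -> tuple[list[SearchArchive], list[ClinicalTimeline], dict]:
    """Generate archives, timelines and effect bookkeeping for one cohort.

    Returns ``(archives, timelines, truth)`` where ``truth`` records which
    categories were actually shifted for each task contrast (the diagnostic
    window is an illness period, so both shift sets apply there) along with
    the full effect specification.  Fully deterministic given ``spec.seed``.
    """
    lexicon = lexicon or fixture_lexicon()
    if lexicon.n_categories != len(
        _weight_vector(lexicon, spec.category_weights)
    ):  # pragma: no cover - defensive
        raise SpecError("weight vector length mismatch")
    vocab = _vocab_lists(lexicon)

    archives: list[SearchArchive] = []
    timelines: list[ClinicalTimeline] = []
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_ssd + spec.n_hv)
    k = 0
    for i in range(spec.n_ssd):
        pid = f"ssd{i + 1:03d}"
        rng = np.random.default_rng(children[k]); k += 1
        timeline = _draw_timeline(rng, spec, pid)
        timelines.append(timeline)
        archives.append(
            _generate_participant(rng, spec, pid, "SSD", timeline, lexicon, vocab)
        )
    for i in range(spec.n_hv):
        pid = f"hv{i + 1:03d}"
        rng = np.random.default_rng(children[k]); k += 1
        timelines.append(ClinicalTimeline(pid, "HV", []))
        archives.append(
            _generate_participant(rng, spec, pid, "HV", None, lexicon, vocab)
        )

    eff = spec.effect
    truth = {
        "diagnostic_shifted_categories": sorted(
            set(eff.diagnostic_category_shift) | set(eff.relapse_category_shift)
        ),
        "relapse_shifted_categories": sorted(eff.relapse_category_shift),
        "effect": asdict(eff),
        "seed": spec.seed,
    }
    return archives, timelines, truth
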