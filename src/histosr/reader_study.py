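"""Blinded HR-vs-RHR reader-study construction and scoring.

Two instruments are supported, mirroring how reconstructed slides are
evaluated by pathologists: (1) a subjective review in which each
reconstructed image is marked as showing a diagnosis-affecting difference
or not, and rated for diagnostic confidence (authenticity / confidence
rates); and (2) a two-alternative forced choice in which the rater picks
which of two blinded images is the true high-resolution scan.  Forced-choice
accuracy near 50% means the reconstruction is indistinguishable from the
real scan, which is the desired outcome — the guessing null distribution is
simulated to make "near 50%" precise.

Category averages are unweighted means of the per-category percentages (not
pooled counts); that is the arithmetic used throughout the summary tables.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CandidatePair",
    "Trial",
    "TrialSet",
    "Counts",
    "StudyResult",
    "build_trials",
    "emit_trial_package",
    "score_answers",
    "accuracy_rate",
    "accuracy_rate_average",
    "authenticity_rate",
    "authenticity_rate_average",
    "confidence_rate",
    "confidence_rate_average",
    "null_distribution",
    "NullDistribution",
]


@dataclass(frozen=True)
class CandidatePair:
    """One HR/RHR image pair with explicit arm labels (validated)."""

    image_1: str
    label_1: str
    image_2: str
    label_2: str
    category: str

    def __post_init__(self) -> None:
        labels = {self.label_1, self.label_2}
        if labels != {"hr", "rhr"}:
            raise ValueError(
                f"each pair needs exactly one 'hr' and one 'rhr' arm, got {labels}"
            )

    @property
    def hr(self) -> str:
        return self.image_1 if self.label_1 == "hr" else self.image_2

    @property
    def rhr(self) -> str:
        return self.image_1 if self.label_1 == "rhr" else self.image_2


@dataclass(frozen=True)
class Trial:
    trial_id: int
    image_a: str
    image_b: str
    key: str         # 'a' or 'b': which presented arm is the true HR image
    category: str


@dataclass
class TrialSet:
    trials: list[Trial]
    seed: int

    def __post_init__(self) -> None:
        seen = set()
        per_cat: dict[str, int] = {}
        bal: dict[str, int] = {}
        for t in self.trials:
            pair = frozenset((t.image_a, t.image_b))
            if pair in seen:
                raise ValueError("duplicate image pair in trial set")
            seen.add(pair)
            per_cat[t.category] = per_cat.get(t.category, 0) + 1
            bal[t.category] = bal.get(t.category, 0) + (1 if t.key == "a" else -1)
        for cat, imbalance in bal.items():
            if abs(imbalance) > 1:
                raise ValueError(f"key assignment unbalanced in category {cat!r}")


def build_trials(pairs, seed: int = 0) -> TrialSet:
    """Randomize presentation order and assign balanced, blinded keys.

    ``pairs`` is a sequence of :class:`CandidatePair`.  Within each category
    the HR image is presented as arm 'a' in exactly half the trials (within
    1 for odd counts); order and assignment are deterministic per seed.
    """
    pairs = list(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    # balanced key pattern per category, shuffled
    by_cat: dict[str, list[int]] = {}
    for idx in order:
        by_cat.setdefault(pairs[idx].category, []).append(int(idx))
    key_of: dict[int, str] = {}
    for cat, idxs in by_cat.items():
        keys = ["a", "b"] * (len(idxs) // 2 + 1)
        keys = keys[: len(idxs)]
        keys = [keys[i] for i in rng.permutation(len(keys))]
        for idx, k in zip(idxs, keys):
            key_of[idx] = k
    trials = []
    for tid, idx in enumerate(order):
        p = pairs[idx]
        k = key_of[int(idx)]
        a, b = (p.hr, p.rhr) if k == "a" else (p.rhr, p.hr)
        trials.append(Trial(trial_id=tid, image_a=a, image_b=b, key=k,
                            category=p.category))
    return TrialSet(trials=trials, seed=seed)


def emit_trial_package(trialset: TrialSet, out_dir: str) -> str:
    """Write the blinded presentation package plus a separate key file.

    ``presentation/`` holds renamed image copies and an answer-sheet
    template with no method metadata anywhere; ``key.tsv`` (outside the
    presentation directory) records the ground truth.
    """
    pres = os.path.join(out_dir, "presentation")
    os.makedirs(pres, exist_ok=True)
    sheet = os.path.join(pres, "answer_sheet.tsv")
    with open(sheet, "w") as fh:
        fh.write("trial_id\tchosen_arm\tmarked_different\tconfident\n")
        for t in trialset.trials:
            for arm, src in (("a", t.image_a), ("b", t.image_b)):
                ext = os.path.splitext(src)[1] or ".png"
                shutil.copyfile(src, os.path.join(pres, f"trial{t.trial_id:04d}_{arm}{ext}"))
            fh.write(f"{t.trial_id}\t\t\t\n")
    with open(os.path.join(out_dir, "key.tsv"), "w") as fh:
        fh.write("trial_id\tkey\tcategory\n")
        for t in trialset.trials:
            fh.write(f"{t.trial_id}\t{t.key}\t{t.category}\n")
    return pres


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class Counts:
    correct: int = 0
    incorrect: int = 0
    authenticity_marked_different: int = 0
    authenticity_total: int = 0
    confident: int = 0
    confidence_total: int = 0

    def __post_init__(self) -> None:
        for f in (self.correct, self.incorrect, self.authenticity_marked_different,
                  self.authenticity_total, self.confident, self.confidence_total):
            if f < 0:
                raise ValueError("counts must be non-negative")


@dataclass
class StudyResult:
    """Per-(rater, category) counts."""

    counts: dict[tuple[str, str], Counts] = field(default_factory=dict)

    def get(self, rater: str, category: str) -> Counts:
        key = (rater, category)
        if key not in self.counts:
            raise KeyError(f"no counts for rater {rater!r}, category {category!r}")
        return self.counts[key]

    def categories(self, rater: str) -> list[str]:
        return [c for (r, c) in self.counts if r == rater]


def score_answers(trialset: TrialSet, answers, rater: str) -> StudyResult:
    """Score a completed answer sheet against the trial key.

    ``answers`` maps trial_id -> dict with keys ``chosen_arm`` ('a'/'b') and
    optional booleans ``marked_different`` and ``confident``.
    """
    result = StudyResult()
    for t in trialset.trials:
        if t.trial_id not in answers:
            continue
        ans = answers[t.trial_id]
        key = (rater, t.category)
        c = result.counts.setdefault(key, Counts())
        chosen = ans.get("chosen_arm")
        if chosen is not None:
            if chosen == t.key:
                c.correct += 1
            else:
                c.incorrect += 1
        if "marked_different" in ans:
            c.authenticity_total += 1
            c.authenticity_marked_different += bool(ans["marked_different"])
        if "confident" in ans:
            c.confidence_total += 1
            c.confident += bool(ans["confident"])
    return result


def _pct(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise ValueError(f"zero {what} items")
    return 100.0 * num / den


def accuracy_rate(result: StudyResult, rater: str, category: str) -> float:
    """100 * correct / (correct + incorrect)."""
    c = result.get(rater, category)
    return _pct(c.correct, c.correct + c.incorrect, "forced-choice")


def authenticity_rate(result: StudyResult, rater: str, category: str) -> float:
    """100 * (total - marked_different) / total."""
    c = result.get(rater, category)
    return _pct(c.authenticity_total - c.authenticity_marked_different,
                c.authenticity_total, "authenticity")


def confidence_rate(result: StudyResult, rater: str, category: str) -> float:
    """100 * confident / confidence_total."""
    c = result.get(rater, category)
    return _pct(c.confident, c.confidence_total, "confidence")


def _average(fn, result: StudyResult, rater: str) -> float:
    cats = result.categories(rater)
    if not cats:
        raise ValueError(f"no categories for rater {rater!r}")
    return float(np.mean([fn(result, rater, c) for c in cats]))


def accuracy_rate_average(result: StudyResult, rater: str) -> float:
    """Plain mean of the per-category accuracy percentages."""
    return _average(accuracy_rate, result, rater)


def authenticity_rate_average(result: StudyResult, rater: str) -> float:
    return _average(authenticity_rate, result, rater)


def confidence_rate_average(result: StudyResult, rater: str) -> float:
    return _average(confidence_rate, result, rater)


# ---------------------------------------------------------------------------
# guessing null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    accuracies: np.ndarray   # simulated accuracy percentages under guessing
    n_trials: int

    def exceedance_p(self, observed_pct: float) -> float:
        """Two-sided probability of a guessing accuracy at least as far from
        50% as the observation."""
        dev = abs(observed_pct - 50.0)
        return float(np.mean(np.abs(self.accuracies - 50.0) >= dev - 1e-12))

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(self.accuracies, lo)),
                float(np.quantile(self.accuracies, 1.0 - lo)))


def null_distribution(n_trials: int, n_reps: int = 100_000, seed: int = 0) -> NullDistribution:
    """Simulate forced-choice accuracy under pure guessing (binomial p=0.5)."""
    if n_trials <= 0 or n_reps <= 0:
        raise ValueError("n_trials and n_reps must be positive")
    rng = np.random.default_rng(seed)
    correct = rng.binomial(n_trials, 0.5, size=n_reps)
    return NullDistribution(accuracies=100.0 * correct / n_trials, n_trials=n_trials)
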