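"""Trial-level response scoring and fusion-table construction.

Free-text syllable reports to McGurk stimuli are assigned to four mutually
exclusive categories — auditory, visual, fusion, other — with half-point
scoring for double-syllable stimuli ("bada" to an auditory-"baba" /
visual-"gaga" stimulus scores 0.5 auditory + 0.5 fusion). Fusion percepts
are "da", "ta" or "tha" (and their doublings). Per-participant congruent
accuracy gates inclusion: participants below the accuracy threshold
(default 90%) are excluded before any model fitting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .romanization import normalize_response

logger = logging.getLogger(__name__)

#: Syllables counted as fusion percepts, regardless of stimulus.
FUSION_SYLLABLES = frozenset({"da", "ta", "tha"})


@dataclass(frozen=True)
class TrialRecord:
    """One response event: a participant's typed report to one video."""

    participant_id: str
    stimulus_id: str
    repetition: int
    raw_response: str
    stimulus_kind: str  # "mcgurk" | "congruent"

    def __post_init__(self) -> None:
        if self.repetition < 1:
            raise ValueError(f"repetition must be >= 1, got {self.repetition}")
        if self.stimulus_kind not in ("mcgurk", "congruent"):
            raise ValueError(f"unknown stimulus_kind {self.stimulus_kind!r}")
        if not self.raw_response.strip():
            raise ValueError("raw_response is empty")


@dataclass(frozen=True)
class ResponseScore:
    """Fractional assignment of one response over the four categories."""

    auditory: float = 0.0
    visual: float = 0.0
    fusion: float = 0.0
    other: float = 0.0

    def __post_init__(self) -> None:
        total = self.auditory + self.visual + self.fusion + self.other
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"category fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class StimulusSpec:
    """Metadata and category form-sets for one audiovisual stimulus.

    ``fusion_forms`` / ``auditory_forms`` / ``visual_forms`` are the
    pairwise-disjoint whole-response strings accepted for each category.
    For double-syllable stimuli they include both the doubled forms
    ("dada") and the single-mora forms ("da"), so an unsplittable single
    syllable typed against a doubled stimulus is still categorized.
    """

    stimulus_id: str
    auditory_syllable: str
    visual_syllable: str
    fusion_forms: frozenset[str]
    auditory_forms: frozenset[str]
    visual_forms: frozenset[str]
    n_syllables: int
    voicing: str  # "voiced" | "unvoiced"
    talker_gender: str = "unknown"
    talker_native_japanese: bool = False
    fusion_percept: str = ""  # canonical fusion report, e.g. "dada"

    def __post_init__(self) -> None:
        if self.n_syllables not in (1, 2):
            raise ValueError("n_syllables must be 1 or 2")
        if self.voicing not in ("voiced", "unvoiced"):
            raise ValueError(f"voicing must be voiced/unvoiced, got {self.voicing!r}")
        for a, b in itertools.combinations(
            (self.fusion_forms, self.auditory_forms, self.visual_forms), 2
        ):
            if a & b:
                raise ValueError(f"category form-sets overlap: {sorted(a & b)}")

    @property
    def auditory_unit(self) -> str:
        """Single-mora auditory form ('ba' for both 'ba' and 'baba')."""
        s = self.auditory_syllable
        return s[: len(s) // 2] if self.n_syllables == 2 else s

    @property
    def visual_unit(self) -> str:
        s = self.visual_syllable
        return s[: len(s) // 2] if self.n_syllables == 2 else s


def make_stimulus_spec(
    stimulus_id: str,
    auditory_syllable: str,
    visual_syllable: str,
    voicing: str,
    talker_gender: str = "unknown",
    talker_native_japanese: bool = False,
    fusion_percept: str | None = None,
) -> StimulusSpec:
    """Build a :class:`StimulusSpec` with derived form-sets.

    A syllable string that is an exact doubling of its first half
    ("baba", "kaka") marks a double-syllable stimulus.
    """
    aud, vis = auditory_syllable, visual_syllable
    doubled = len(aud) >= 4 and len(aud) % 2 == 0 and aud[: len(aud) // 2] * 2 == aud
    n_syll = 2 if doubled else 1
    fusion_units = set(FUSION_SYLLABLES)
    if n_syll == 1:
        fusion_forms = frozenset(fusion_units)
        auditory_forms = frozenset({aud})
        visual_forms = frozenset({vis})
        default_percept = "ta" if voicing == "unvoiced" else "da"
    else:
        fusion_forms = frozenset(
            fusion_units | {u + v for u in fusion_units for v in fusion_units}
        )
        auditory_forms = frozenset({aud, aud[: len(aud) // 2]})
        visual_forms = frozenset({vis, vis[: len(vis) // 2]})
        default_percept = "tata" if voicing == "unvoiced" else "dada"
    return StimulusSpec(
        stimulus_id=stimulus_id,
        auditory_syllable=aud,
        visual_syllable=vis,
        fusion_forms=fusion_forms,
        auditory_forms=auditory_forms,
        visual_forms=visual_forms,
        n_syllables=n_syll,
        voicing=voicing,
        talker_gender=talker_gender,
        talker_native_japanese=talker_native_japanese,
        fusion_percept=fusion_percept or default_percept,
    )


def make_congruent_spec(
    stimulus_id: str, syllable: str, talker_gender: str = "unknown"
) -> StimulusSpec:
    """Spec for a congruent control stimulus (audio and video identical).

    Congruent trials are scored only for accuracy (response == syllable),
    so the category form-sets reduce to the auditory form.
    """
    voicing = "unvoiced" if syllable[0] in ("p", "k", "t") else "voiced"
    return StimulusSpec(
        stimulus_id=stimulus_id,
        auditory_syllable=syllable,
        visual_syllable=syllable,
        fusion_forms=frozenset(),
        auditory_forms=frozenset({syllable}),
        visual_forms=frozenset(),
        n_syllables=1,
        voicing=voicing,
        talker_gender=talker_gender,
    )


def _whole_unit_score(normalized: str, spec: StimulusSpec) -> ResponseScore:
    if normalized in spec.fusion_forms:
        return ResponseScore(fusion=1.0)
    if normalized in spec.auditory_forms:
        return ResponseScore(auditory=1.0)
    if normalized in spec.visual_forms:
        return ResponseScore(visual=1.0)
    return ResponseScore(other=1.0)


def _unit_category(unit: str, spec: StimulusSpec) -> str:
    if unit in FUSION_SYLLABLES:
        return "fusion"
    if unit == spec.auditory_unit:
        return "auditory"
    if unit == spec.visual_unit:
        return "visual"
    return "other"


def score_response(normalized: str, spec: StimulusSpec) -> ResponseScore:
    """Assign a normalized response to the four categories.

    Single-syllable stimuli: whole-string match against the form-sets;
    anything unmatched is "other". Double-syllable stimuli: the response
    is split into two morae by greedy longest-prefix match against the
    stimulus's known syllable units, each mora contributing 0.5 to its
    category; responses that do not split into exactly two known units
    are scored as one whole unit.
    """
    if spec.n_syllables == 1:
        return _whole_unit_score(normalized, spec)
    known = set(FUSION_SYLLABLES) | {spec.auditory_unit, spec.visual_unit}
    for unit in sorted(known, key=lambda u: (-len(u), u)):
        rest = normalized[len(unit):]
        if normalized.startswith(unit) and rest in known:
            cats = {"auditory": 0.0, "visual": 0.0, "fusion": 0.0, "other": 0.0}
            cats[_unit_category(unit, spec)] += 0.5
            cats[_unit_category(rest, spec)] += 0.5
            return ResponseScore(**cats)
    return _whole_unit_score(normalized, spec)


@dataclass
class FusionTable:
    """Participants x stimuli matrix of fusion proportions.

    ``fusion_prop[j, i]`` is the mean fusion score of participant
    ``participants[j]`` over their repetitions of ``stimuli[i]``; cells
    with no trials are NaN (missing), never zero. ``n_reps`` records how
    many trials each cell aggregates.
    """

    participants: list[str]
    stimuli: list[str]
    fusion_prop: np.ndarray
    n_reps: np.ndarray

    def __post_init__(self) -> None:
        self.fusion_prop = np.asarray(self.fusion_prop, dtype=float)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        shape = (len(self.participants), len(self.stimuli))
        if self.fusion_prop.shape != shape or self.n_reps.shape != shape:
            raise ValueError("matrix shapes do not match axis labels")
        vals = self.fusion_prop[~np.isnan(self.fusion_prop)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("fusion proportions outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fusion_prop.shape

    def stimulus_means(self) -> np.ndarray:
        """Mean fusion per stimulus across participants (missing excluded)."""
        return np.nanmean(self.fusion_prop, axis=0)

    def participant_means(self) -> np.ndarray:
        return np.nanmean(self.fusion_prop, axis=1)

    def grand_mean(self) -> float:
        """Average across participants of per-participant mean fusion."""
        return float(np.nanmean(self.participant_means()))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: participant_id, stimulus_id, fusion_prop, n_reps."""
        j, i = np.meshgrid(
            np.arange(len(self.participants)), np.arange(len(self.stimuli)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "participant_id": np.asarray(self.participants)[j.ravel()],
                "stimulus_id": np.asarray(self.stimuli)[i.ravel()],
                "fusion_prop": self.fusion_prop.ravel(),
                "n_reps": self.n_reps.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FusionTable":
        participants = sorted(df["participant_id"].astype(str).unique())
        stimuli = list(pd.unique(df["stimulus_id"].astype(str)))
        prop = np.full((len(participants), len(stimuli)), np.nan)
        reps = np.zeros((len(participants), len(stimuli)), dtype=int)
        pidx = {p: j for j, p in enumerate(participants)}
        sidx = {s: i for i, s in enumerate(stimuli)}
        for row in df.itertuples(index=False):
            j, i = pidx[str(row.participant_id)], sidx[str(row.stimulus_id)]
            if int(row.n_reps) > 0:
                prop[j, i] = float(row.fusion_prop)
                reps[j, i] = int(row.n_reps)
        return cls(participants, stimuli, prop, reps)


def _as_trial_frame(trials: Iterable) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame([t.__dict__ for t in trials])
    required = {"participant_id", "stimulus_id", "repetition", "raw_response", "stimulus_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def congruent_accuracy(
    trials: Iterable, specs: Mapping[str, StimulusSpec]
) -> dict[str, float]:
    """Per-participant accuracy on congruent trials.

    A congruent trial is correct when the normalized response equals the
    stimulus syllable. Trials that normalize to the empty string are
    flagged invalid and excluded from the denominator. Participants with
    no valid congruent trials get NaN (they cannot pass the filter).
    """
    df = _as_trial_frame(trials)
    df = df[df["stimulus_kind"] == "congruent"]
    acc: dict[str, float] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        correct = total = 0
        for row in grp.itertuples(index=False):
            norm = normalize_response(str(row.raw_response))
            if not norm:
                logger.warning(
                    "flagged-invalid congruent trial: participant=%s stimulus=%s",
                    pid, row.stimulus_id,
                )
                continue
            spec = specs[str(row.stimulus_id)]
            total += 1
            correct += int(norm == spec.auditory_syllable)
        acc[str(pid)] = correct / total if total else float("nan")
        if total == 0:
            logger.warning("participant %s has no valid congruent trials", pid)
    return acc


def filter_participants(
    accuracies: Mapping[str, float], threshold: float = 0.90
) -> tuple[set[str], list[tuple[str, float]]]:
    """Retain participants with congruent accuracy >= ``threshold``.

    Returns the included set and an exclusion log of (participant_id,
    accuracy) pairs; NaN accuracy (no valid congruent trials) always
    excludes. Raises if nobody survives.
    """
    included: set[str] = set()
    excluded: list[tuple[str, float]] = []
    for pid in sorted(accuracies):
        a = accuracies[pid]
        if np.isnan(a) or a < threshold:
            excluded.append((pid, float(a)))
            logger.info("excluding participant %s (congruent accuracy %.3f)", pid, a)
        else:
            included.add(pid)
    if not included:
        raise ValueError(
            f"no participants pass the {threshold:.0%} congruent-accuracy filter"
        )
    return included, excluded


def build_fusion_table(
    trials: Iterable,
    specs: Mapping[str, StimulusSpec],
    included: set[str] | Sequence[str] | None = None,
) -> FusionTable:
    """Aggregate McGurk trials into a participants x stimuli fusion table.

    Each cell is the mean fusion score over that participant's repetitions
    of that stimulus; empty cells stay missing (NaN). Duplicate
    (participant, stimulus, repetition) triples are an error. Trials whose
    response normalizes to the empty string are flagged and dropped.
    """
    df = _as_trial_frame(trials)
    df = df[df["stimulus_kind"] == "mcgurk"].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["stimulus_id"] = df["stimulus_id"].astype(str)
    if included is not None:
        df = df[df["participant_id"].isin(set(included))]
    dupes = df.duplicated(subset=["participant_id", "stimulus_id", "repetition"])
    if dupes.any():
        first = df.loc[dupes.idxmax()]
        raise ValueError(
            "duplicate trial triple: "
            f"({first.participant_id}, {first.stimulus_id}, {first.repetition})"
        )
    participants = sorted(df["participant_id"].unique())
    stimuli = [s for s in specs if s in set(df["stimulus_id"])]
    prop = np.full((len(participants), len(stimuli)), np.nan)
    reps = np.zeros((len(participants), len(stimuli)), dtype=int)
    pidx = {p: j for j, p in enumerate(participants)}
    sidx = {s: i for i, s in enumerate(stimuli)}

    sums = np.zeros_like(prop)
    for row in df.itertuples(index=False):
        norm = normalize_response(str(row.raw_response))
        if not norm:
            logger.warning(
                "flagged-invalid trial dropped: participant=%s stimulus=%s rep=%s",
                row.participant_id, row.stimulus_id, row.repetition,
            )
            continue
        score = score_response(norm, specs[str(row.stimulus_id)])
        j, i = pidx[row.participant_id], sidx[row.stimulus_id]
        sums[j, i] = np.nan_to_num(sums[j, i]) + score.fusion
        reps[j, i] += 1
    with np.errstate(invalid="ignore"):
        prop = np.where(reps > 0, sums / np.maximum(reps, 1), np.nan)
    return FusionTable(participants, stimuli, prop, reps)
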