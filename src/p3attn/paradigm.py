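"""Auditory oddball word-stream paradigm.

Each experimental block is a stream of 90-100 monosyllabic words presented
once every 900-1100 ms.  Two equiprobable target words (YES / NO, 13-16
presentations each per block) are embedded among distractors drawn from a
50-word lexicon.  One target word is designated the *explicit* target for
the block (the subject counts it); the other becomes the *implicit* target.
Apparent spatial location is manipulated through interaural timing
differences (ITDs): targets are fully lateralised at +-660 us (+-90 deg),
distractors take one of seven ITDs between -495 and +495 us, mapping
linearly onto azimuths between -67.5 and +67.5 deg.

This module generates the event structure only (no audio): block and
session samplers plus a lossless TSV event-table round trip.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._words import DISTRACTOR_DURATIONS_MS, DISTRACTOR_WORDS, TARGET_DURATIONS_MS

#: ITDs (microseconds) available to distractor words.
DISTRACTOR_ITDS_US = (-495, -330, -165, 0, 165, 330, 495)

#: Anchor of the linear ITD -> azimuth mapping: +-660 us corresponds to +-90 deg.
TARGET_ITD_US = 660
TARGET_AZIMUTH_DEG = 90.0

CATEGORIES = ("explicit_target", "implicit_target", "distractor")

EVENTS_TSV_COLUMNS = (
    "block",
    "onset_ms",
    "label",
    "category",
    "itd_us",
    "azimuth_deg",
    "duration_ms",
)


class ParadigmError(ValueError):
    """Invalid or infeasible paradigm specification."""


class EventsParseError(ValueError):
    """Malformed events table; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def itd_to_azimuth(itd_us: float) -> float:
    """Map an interaural timing difference to apparent azimuth in degrees.

    The mapping is the straight line through the target anchors
    (+-660 us <-> +-90 deg), i.e. ``90 * itd / 660``.

    Parameters
    ----------
    itd_us : float
        Signed interaural timing difference in microseconds, ``|itd| <= 660``.
    """
    itd_us = float(itd_us)
    if abs(itd_us) > TARGET_ITD_US:
        raise ParadigmError(
            f"|ITD| = {abs(itd_us)} us exceeds the {TARGET_ITD_US} us anchor"
        )
    return TARGET_AZIMUTH_DEG * itd_us / TARGET_ITD_US


def display_azimuth(itd_us: float) -> int:
    """Azimuth rounded to the nearest whole degree, as quoted to subjects.

    E.g. an ITD of 495 us maps to 67.5 deg and displays as 68 deg.
    """
    az = itd_to_azimuth(itd_us)
    # round-half-away-from-zero so +-67.5 displays as +-68
    return int(np.sign(az) * np.floor(abs(az) + 0.5))


@dataclass(frozen=True)
class WordToken:
    """One word presentation within a block."""

    label: str
    category: str
    onset_ms: float
    duration_ms: float
    itd_us: int
    azimuth_deg: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ParadigmError(f"unknown category {self.category!r}")
        if self.category in ("explicit_target", "implicit_target"):
            if abs(self.itd_us) != TARGET_ITD_US or abs(self.azimuth_deg) != 90.0:
                raise ParadigmError("targets must be fully lateralised (+-660 us)")
        else:
            if self.itd_us not in DISTRACTOR_ITDS_US:
                raise ParadigmError(f"distractor ITD {self.itd_us} not allowed")


@dataclass
class BlockSpec:
    """Composition of a single word block."""

    explicit_word: str = "YES"
    n_words_range: tuple[int, int] = (90, 100)
    n_each_target_range: tuple[int, int] = (13, 16)
    soa_range_ms: tuple[float, float] = (900.0, 1100.0)
    target_spacing_range: tuple[int, int] = (2, 8)
    distractor_lexicon: Sequence[str] = DISTRACTOR_WORDS
    seed: int | None = None

    def validate(self) -> None:
        if self.explicit_word not in ("YES", "NO"):
            raise ParadigmError("explicit_word must be 'YES' or 'NO'")
        if len(self.distractor_lexicon) != 50:
            raise ParadigmError(
                f"distractor lexicon must have exactly 50 entries, "
                f"got {len(self.distractor_lexicon)}"
            )
        if len(set(self.distractor_lexicon)) != len(self.distractor_lexicon):
            raise ParadigmError("distractor lexicon entries must be unique")
        lo, hi = self.target_spacing_range
        if not (0 < lo <= hi):
            raise ParadigmError("invalid target spacing range")


@dataclass
class SessionSpec:
    """A full session: a sequence of blocks with counterbalanced target roles."""

    n_blocks: int = 20
    counterbalance: bool = True
    block_spec: BlockSpec = field(default_factory=BlockSpec)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ParadigmError("n_blocks must be >= 1")
        if self.counterbalance and self.n_blocks % 2:
            raise ParadigmError(
                "counterbalancing requires an even number of blocks; "
                f"got {self.n_blocks}"
            )
        self.block_spec.validate()


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _sample_gaps(n_dist: int, n_targets: int, lo: int, hi: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Distractor counts before/between/after targets.

    Returns ``n_targets + 1`` gap sizes summing to ``n_dist``; interior gaps
    (between consecutive targets) lie in ``[lo, hi]``, edge gaps are >= 0.
    Interior gaps start at the minimum and remaining slots are assigned one
    at a time to a uniformly random gap that is still below its cap.
    """
    n_interior = n_targets - 1
    need = lo * n_interior
    if need > n_dist:
        raise ParadigmError(
            f"infeasible block: {n_targets} targets require at least "
            f"{need} distractors for {lo}-{hi} spacing, but only "
            f"{n_dist} distractor slots are available"
        )
    gaps = np.zeros(n_targets + 1, dtype=int)
    gaps[1:-1] = lo
    caps = np.full(n_targets + 1, np.iinfo(np.int64).max)
    caps[1:-1] = hi
    for _ in range(n_dist - need):
        open_idx = np.flatnonzero(gaps < caps)
        gaps[rng.choice(open_idx)] += 1
    return gaps


def generate_block(spec: BlockSpec, rng: np.random.Generator | int | None = None
                   ) -> list[WordToken]:
    """Sample one block of word tokens satisfying the paradigm constraints.

    Targets are placed first (13-16 presentations of each target word,
    consecutive target presentations separated by 2-8 distractors), then the
    distractor positions are filled from the lexicon with no word repeated
    in adjacent positions.  Distractor ITDs are sampled uniformly from the
    seven allowed values; onsets follow inter-onset intervals drawn
    uniformly from ``soa_range_ms``.
    """
    spec.validate()
    rng = _as_rng(spec.seed if rng is None else rng)

    t_lo, t_hi = spec.n_each_target_range
    w_lo, w_hi = spec.n_words_range
    s_lo, s_hi = spec.target_spacing_range
    # smallest possible block: fewest targets at minimum spacing
    if w_hi < 2 * t_lo + s_lo * (2 * t_lo - 1):
        raise ParadigmError(
            f"infeasible spec: {2 * t_lo} targets with >= {s_lo} distractors "
            f"between consecutive presentations need at least "
            f"{2 * t_lo + s_lo * (2 * t_lo - 1)} words, but n_words <= {w_hi}"
        )
    # reject-and-resample draws whose composition cannot satisfy the spacing
    for _ in range(1000):
        n_yes = int(rng.integers(t_lo, t_hi + 1))
        n_no = int(rng.integers(t_lo, t_hi + 1))
        n_words = int(rng.integers(w_lo, w_hi + 1))
        n_targets = n_yes + n_no
        n_dist = n_words - n_targets
        if n_dist >= s_lo * (n_targets - 1):
            break
    else:
        raise ParadigmError(
            "could not draw a feasible block composition: target counts x "
            f"minimum spacing ({s_lo}) almost always exceed n_words"
        )
    gaps = _sample_gaps(n_dist, n_targets, s_lo, s_hi, rng)

    target_labels = ["YES"] * n_yes + ["NO"] * n_no
    rng.shuffle(target_labels)

    implicit_word = "NO" if spec.explicit_word == "YES" else "YES"

    # interleave: gap[0] distractors, target, gap[1] distractors, target, ...
    labels: list[str] = []
    categories: list[str] = []
    t_idx = 0
    for i, g in enumerate(gaps):
        for _ in range(g):
            labels.append(None)  # distractor placeholder
            categories.append("distractor")
        if i < n_targets:
            lab = target_labels[t_idx]
            labels.append(lab)
            categories.append(
                "explicit_target" if lab == spec.explicit_word else "implicit_target"
            )
            t_idx += 1

    # fill distractor labels with no immediate repeats (targets included:
    # no two adjacent tokens may share a label)
    lexicon = list(spec.distractor_lexicon)
    prev: str | None = None
    for i, lab in enumerate(labels):
        if lab is None:
            labels[i] = lexicon[int(rng.integers(len(lexicon)))]
            while labels[i] == prev:
                labels[i] = lexicon[int(rng.integers(len(lexicon)))]
        prev = labels[i]

    iois = rng.uniform(*spec.soa_range_ms, size=n_words)
    onsets = np.concatenate([[0.0], np.cumsum(iois[:-1])])

    tokens: list[WordToken] = []
    for onset, lab, cat in zip(onsets, labels, categories):
        if cat == "distractor":
            itd = int(rng.choice(DISTRACTOR_ITDS_US))
            dur = DISTRACTOR_DURATIONS_MS.get(lab, 550)
        else:
            itd = -TARGET_ITD_US if lab == "YES" else TARGET_ITD_US
            dur = TARGET_DURATIONS_MS[lab]
        tokens.append(
            WordToken(
                label=lab,
                category=cat,
                onset_ms=float(onset),
                duration_ms=float(dur),
                itd_us=itd,
                azimuth_deg=itd_to_azimuth(itd),
            )
        )
    return tokens


def generate_session(spec: SessionSpec, rng: np.random.Generator | int | None = None
                     ) -> list[list[WordToken]]:
    """Sample a full session of blocks with counterbalanced explicit words.

    With counterbalancing, exactly half the blocks have YES as the explicit
    target; block order is randomised.  Per-block seeds are derived from the
    session seed through ``numpy.random.SeedSequence.spawn`` so each block is
    independently reproducible.
    """
    spec.validate()
    if rng is None:
        rng = spec.seed
    if isinstance(rng, np.random.Generator):
        seq = np.random.SeedSequence(int(rng.integers(2**31)))
    else:
        seq = np.random.SeedSequence(rng)
    order_rng = np.random.default_rng(seq.spawn(1)[0])
    block_seqs = seq.spawn(spec.n_blocks)

    if spec.counterbalance:
        words = ["YES"] * (spec.n_blocks // 2) + ["NO"] * (spec.n_blocks // 2)
    else:
        words = [
            "YES" if order_rng.random() < 0.5 else "NO"
            for _ in range(spec.n_blocks)
        ]
    order_rng.shuffle(words)

    blocks = []
    for word, bseq in zip(words, block_seqs):
        bspec = replace(spec.block_spec, explicit_word=word)
        blocks.append(generate_block(bspec, np.random.default_rng(bseq)))
    return blocks


def session_to_frame(blocks: list[list[WordToken]]) -> pd.DataFrame:
    """Flatten a session into an event table (one row per token)."""
    rows = []
    for b, tokens in enumerate(blocks):
        for tok in tokens:
            rows.append(
                {
                    "block": b,
                    "onset_ms": tok.onset_ms,
                    "label": tok.label,
                    "category": tok.category,
                    "itd_us": tok.itd_us,
                    "azimuth_deg": tok.azimuth_deg,
                    "duration_ms": tok.duration_ms,
                }
            )
    return pd.DataFrame(rows, columns=list(EVENTS_TSV_COLUMNS))


def frame_to_session(events: pd.DataFrame) -> list[list[WordToken]]:
    """Rebuild the per-block token lists from an event table."""
    blocks = []
    for _, grp in events.groupby("block", sort=True):
        blocks.append(
            [
                WordToken(
                    label=r.label,
                    category=r.category,
                    onset_ms=float(r.onset_ms),
                    duration_ms=float(r.duration_ms),
                    itd_us=int(r.itd_us),
                    azimuth_deg=float(r.azimuth_deg),
                )
                for r in grp.itertuples()
            ]
        )
    return blocks


def write_events_tsv(blocks_or_frame, path) -> None:
    """Write an events table as UTF-8, tab-separated, one header row."""
    if isinstance(blocks_or_frame, pd.DataFrame):
        frame = blocks_or_frame
    else:
        frame = session_to_frame(blocks_or_frame)
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_events_tsv(path) -> pd.DataFrame:
    """Read an events table, validating every row.

    Raises
    ------
    EventsParseError
        On a missing column or a row whose numeric fields fail to parse;
        the error message carries the 1-based line number.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EventsParseError("empty file", 1) from None
        missing = [c for c in EVENTS_TSV_COLUMNS if c not in header]
        if missing:
            raise EventsParseError(f"missing column(s) {missing}", 1)
        idx = {c: header.index(c) for c in EVENTS_TSV_COLUMNS}
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise EventsParseError(
                    f"expected {len(header)} fields, found {len(row)}", lineno
                )
            try:
                rows.append(
                    {
                        "block": int(float(row[idx["block"]])),
                        "onset_ms": float(row[idx["onset_ms"]]),
                        "label": row[idx["label"]],
                        "category": row[idx["category"]],
                        "itd_us": int(float(row[idx["itd_us"]])),
                        "azimuth_deg": float(row[idx["azimuth_deg"]]),
                        "duration_ms": float(row[idx["duration_ms"]]),
                    }
                )
            except ValueError as exc:
                raise EventsParseError(str(exc), lineno) from None
    return pd.DataFrame(rows, columns=list(EVENTS_TSV_COLUMNS))
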