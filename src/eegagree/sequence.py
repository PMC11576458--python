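"""Auditory oddball stimulus sequences.

The paradigm interleaves two rare deviant tones among frequent standard
tones under a pseudo-randomization constraint: between any two consecutive
deviants (of either type) there are at least ``min_gap`` and at most
``max_gap`` standards.  A short run of habituation standards precedes the
experimental block and is never analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

STANDARD = "standard"
DEVIANT_LOW = "deviant_low"
DEVIANT_HIGH = "deviant_high"
TONES = (STANDARD, DEVIANT_LOW, DEVIANT_HIGH)


class InfeasibleSequenceError(ValueError):
    """Raised when the requested tone counts cannot satisfy the gap bounds."""


@dataclass
class StimulusEvent:
    onset_time: float
    onset_sample: int
    tone: str
    is_habituation: bool
    follows_deviant: bool


@dataclass
class StimulusSequence:
    """Ordered tone events with a fixed stimulus-onset asynchrony."""

    events: List[StimulusEvent]
    soa: float

    @property
    def experimental_events(self) -> List[StimulusEvent]:
        return [e for e in self.events if not e.is_habituation]

    def counts(self) -> dict:
        exp = self.experimental_events
        return {tone: sum(1 for e in exp if e.tone == tone) for tone in TONES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": [e.onset_sample for e in self.events],
                "onset_s": [e.onset_time for e in self.events],
                "tone": [e.tone for e in self.events],
                "is_habituation": [e.is_habituation for e in self.events],
                "follows_deviant": [e.follows_deviant for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, soa: float | None = None) -> "StimulusSequence":
        df = pd.read_csv(path, sep="\t")
        events = [
            StimulusEvent(
                onset_time=float(r.onset_s),
                onset_sample=int(r.onset_sample),
                tone=str(r.tone),
                is_habituation=bool(r.is_habituation),
                follows_deviant=bool(r.follows_deviant),
            )
            for r in df.itertuples()
        ]
        if soa is None:
            if len(events) >= 2:
                soa = events[1].onset_time - events[0].onset_time
            else:
                raise ValueError("cannot infer soa from fewer than 2 events")
        return cls(events=events, soa=float(soa))


def _tone_order(
    n_standards: int,
    n_deviants_per_type: int,
    min_gap: int,
    max_gap: int,
    rng: np.random.Generator,
) -> List[str]:
    """Draw a tone order satisfying the between-deviant gap bounds.

    Gap lengths between consecutive deviants are sampled uniformly from
    ``{min_gap, ..., max_gap}`` and the total is repaired by seeded
    single-step adjustments.  Standards left over after the between-deviant
    gaps are split between the run-in (before the first deviant) and
    run-out (after the last deviant); each end may hold at most ``max_gap``
    standards, which fixes the feasibility window:

        min_gap * (n_dev - 1) <= n_standards <= max_gap * (n_dev + 1)
    """
    n_dev = 2 * n_deviants_per_type
    if n_dev == 0:
        return [STANDARD] * n_standards

    n_gaps = n_dev - 1
    lo = min_gap * n_gaps
    hi = max_gap * n_gaps + 2 * max_gap
    if not lo <= n_standards <= hi:
        raise InfeasibleSequenceError(
            f"{n_standards} standards cannot be arranged around {n_dev} "
            f"deviants with gaps in [{min_gap}, {max_gap}] "
            f"(feasible range: [{lo}, {hi}])"
        )

    # between-deviant gaps plus two end segments (0..max_gap each)
    gaps = rng.integers(min_gap, max_gap + 1, size=n_gaps).tolist() if n_gaps else []
    ends = [0, 0]
    deficit = n_standards - sum(gaps)
    while deficit != 0:
        if deficit > 0:
            grow_ends = [i for i in range(2) if ends[i] < max_gap]
            grow_gaps = [i for i in range(n_gaps) if gaps[i] < max_gap]
            # prefer filling the ends so gap statistics stay uniform
            if grow_ends:
                ends[int(rng.integers(len(grow_ends)))] += 1
            else:
                gaps[grow_gaps[int(rng.integers(len(grow_gaps)))]] += 1
            deficit -= 1
        else:
            shrink = [i for i in range(n_gaps) if gaps[i] > min_gap]
            gaps[shrink[int(rng.integers(len(shrink)))]] -= 1
            deficit += 1

    # assign the deviant subtype uniformly at random over deviant slots
    subtype = np.array(
        [DEVIANT_LOW] * n_deviants_per_type + [DEVIANT_HIGH] * n_deviants_per_type
    )
    rng.shuffle(subtype)

    order: List[str] = [STANDARD] * ends[0]
    for i in range(n_dev):
        order.append(str(subtype[i]))
        if i < n_gaps:
            order.extend([STANDARD] * gaps[i])
    order.extend([STANDARD] * ends[1])
    return order


def generate_sequence(
    n_standards: int = 612,
    n_deviants_per_type: int = 102,
    min_gap: int = 2,
    max_gap: int = 4,
    soa: float = 1.555,
    n_habituation: int = 10,
    seed: int = 0,
    fs: float = 1024.0,
    t0: float = 2.0,
) -> StimulusSequence:
    """Generate a pseudo-randomized oddball sequence.

    Defaults follow the two-deviant design: 612 standards (75 %),
    102 + 102 deviants (12.5 % each), SOA 1.555 s, 10 habituation
    standards delivered before the experimental block.

    Parameters
    ----------
    fs : float
        Sampling rate used to express onsets in samples (1024 Hz for the
        simulated acquisition).
    t0 : float
        Onset time of the first event, leaving a lead-in so that even the
        widest analysis epoch of the first event stays in bounds.
    """
    if soa <= 0:
        raise ValueError("soa must be positive")
    rng = np.random.default_rng(seed)
    order = _tone_order(n_standards, n_deviants_per_type, min_gap, max_gap, rng)

    events: List[StimulusEvent] = []
    t = float(t0)
    for _ in range(n_habituation):
        events.append(
            StimulusEvent(t, int(round(t * fs)), STANDARD, True, False)
        )
        t += soa
    prev_was_deviant = False
    for tone in order:
        events.append(
            StimulusEvent(t, int(round(t * fs)), tone, False, prev_was_deviant)
        )
        prev_was_deviant = tone != STANDARD
        t += soa
    return StimulusSequence(events=events, soa=soa)


def validate_sequence(
    seq: StimulusSequence,
    n_standards: int = 612,
    n_deviants_per_type: int = 102,
    min_gap: int = 2,
    max_gap: int = 4,
    n_habituation: int = 10,
) -> List[str]:
    """Independent constraint checker; returns a list of violations.

    Checks tone counts, habituation placement, the between-deviant gap
    bounds, equal SOA spacing and the post-deviant flags from scratch,
    without reusing any generator internals.
    """
    problems: List[str] = []
    hab = [e for e in seq.events if e.is_habituation]
    if len(hab) != n_habituation:
        problems.append(f"expected {n_habituation} habituation events, got {len(hab)}")
    if any(e.tone != STANDARD for e in hab):
        problems.append("habituation events must all be standards")
    first_exp = next((i for i, e in enumerate(seq.events) if not e.is_habituation), None)
    if first_exp is not None and any(e.is_habituation for e in seq.events[first_exp:]):
        problems.append("habituation events must precede all experimental events")

    exp = seq.experimental_events
    counts = seq.counts()
    if counts[STANDARD] != n_standards:
        problems.append(f"expected {n_standards} standards, got {counts[STANDARD]}")
    for tone in (DEVIANT_LOW, DEVIANT_HIGH):
        if counts[tone] != n_deviants_per_type:
            problems.append(f"expected {n_deviants_per_type} {tone}, got {counts[tone]}")

    dev_idx = [i for i, e in enumerate(exp) if e.tone != STANDARD]
    for a, b in zip(dev_idx, dev_idx[1:]):
        gap = b - a - 1
        if not min_gap <= gap <= max_gap:
            problems.append(f"gap of {gap} standards between deviants at {a} and {b}")

    onsets = np.array([e.onset_time for e in seq.events])
    if len(onsets) >= 2 and not np.allclose(np.diff(onsets), seq.soa, atol=1e-9):
        problems.append("onsets are not uniformly spaced by soa")

    for i, e in enumerate(exp):
        expected = i > 0 and exp[i - 1].tone != STANDARD
        if e.follows_deviant != expected:
            problems.append(f"follows_deviant flag wrong at experimental index {i}")
            break
    return problems
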