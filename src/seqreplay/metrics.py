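"""Recall and replay metrics.

Recall accuracy is the percentage of target items whose cortical activations
cross the recall threshold in the correct order, counted as the longest
correct prefix before any out-of-order (or foreign) crossing; recall time is
the interval from cue onset to the final crossing of a 100%-accurate recall,
and is pinned to the 30 s ceiling otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "RecallResult",
    "recall_accuracy",
    "recall_time",
    "replay_statistics",
]

RECALL_CEILING = 30.0


@dataclass
class RecallResult:
    cue: str
    target: tuple[str, ...]
    crossings: tuple[tuple[str, float], ...]   # (item, s since cue onset)
    accuracy: float                            # percent
    recall_time: float                         # seconds
    day: int | None = None
    time: float | None = None                  # absolute clock at cue onset

    @classmethod
    def from_crossings(cls, cue: str, target: Sequence[str],
                       crossings: Sequence[tuple[str, float]],
                       ceiling: float = RECALL_CEILING,
                       **meta) -> "RecallResult":
        acc = recall_accuracy([c for c, _ in crossings], target)
        rt = recall_time(crossings, target, acc, ceiling=ceiling)
        return cls(cue=cue, target=tuple(target), crossings=tuple(crossings),
                   accuracy=acc, recall_time=rt, **meta)


def _dedup_first(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


def recall_accuracy(crossings: Sequence[str], target: Sequence[str]) -> float:
    """Percent of target items recalled in order before the first error.

    ``crossings`` is the ordered list of items that crossed threshold
    (deduplicated here to each item's first crossing).  Credit accrues while
    the crossing order follows the target order; the first out-of-order or
    non-target crossing ends the count.
    """
    if len(target) == 0:
        raise ValueError("target sequence must be non-empty")
    order = _dedup_first(crossings)
    k = 0
    for item in order:
        if k >= len(target):
            break
        if item == target[k]:
            k += 1
        else:
            break
    return 100.0 * k / len(target)


def recall_time(crossings: Sequence[tuple[str, float]], target: Sequence[str],
                accuracy: float, ceiling: float = RECALL_CEILING) -> float:
    """Cue onset to the final correct crossing; the ceiling if accuracy < 100%."""
    if accuracy < 100.0:
        return ceiling
    seen: set[str] = set()
    last = ceiling
    want = set(target)
    for item, t in crossings:
        if item in want and item not in seen:
            seen.add(item)
            last = t
            if len(seen) == len(want):
                break
    return last if last < ceiling else ceiling


def replay_statistics(records: Sequence, sequences: Mapping[str, Sequence[str]]):
    """Per-night cue histograms, replay shares and full-replay durations.

    ``records`` are :class:`~seqreplay.replay.ReplayRecord` objects.  The
    share of a sequence on a night is the fraction (percent) of non-null
    cued UP states whose cue item belongs to that sequence; cue items not in
    any sequence are pooled under ``"unattributed"``.  Returns a dict keyed
    by night index.
    """
    item_to_seq: dict[str, str] = {}
    for name, items in sequences.items():
        for it in items:
            item_to_seq.setdefault(it, name)

    nights: dict[int, list] = {}
    for rec in records:
        nights.setdefault(rec.night_index, []).append(rec)

    summary: dict[int, dict] = {}
    for night, recs in sorted(nights.items()):
        hist: Counter[str] = Counter()
        attributed: Counter[str] = Counter()
        durations: dict[str, list[float]] = {}
        n_cued = 0
        for rec in recs:
            cue = rec.cue_item
            if cue is None:
                continue
            n_cued += 1
            hist[cue] += 1
            seq = item_to_seq.get(cue)
            if seq is None:
                import warnings
                warnings.warn(f"cue item {cue!r} not in any known sequence")
                attributed["unattributed"] += 1
            else:
                attributed[seq] += 1
                if rec.full_replay and rec.duration is not None:
                    durations.setdefault(seq, []).append(rec.duration)
        shares = (
            {k: 100.0 * v / n_cued for k, v in attributed.items()}
            if n_cued else None
        )
        summary[night] = {
            "cue_histogram": dict(hist),
            "n_cued": n_cued,
            "n_null": len(recs) - n_cued,
            "shares": shares,
            "mean_full_replay_duration": {
                k: sum(v) / len(v) for k, v in durations.items()
            },
        }
    return summary
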