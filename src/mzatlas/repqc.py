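"""IgH amplicon read processing and sequence-level quality control.

Read-level stages (in order): mean-quality/length filter, exact MID
demultiplexing at both read ends, primer matching (forward primer masked
with Ns, reverse primer trimmed, isotype inferred from the reverse
constant-region primer), duplicate collapse on (sequence, MID, forward
primer, reverse primer).

Sequence-level stages on annotated rearrangements: functionality /
MID-consistency filtering, the sliding-window chimera rule (remove if any
10-bp window against the germline holds more than five mutations), and
mutation counting against the germline alignment with junction/N positions
excluded.

Every stage conserves counts: retained + removed == input, per reason.
Mean quality is computed on raw Phred scores, not error probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Read = tuple[str, str, str]  # (read id, sequence, phred33 quality string)


@dataclass
class AnnotatedRead:
    read_id: str
    sequence: str
    mid: str
    fwd_primer: str | None = None
    rev_primer: str | None = None
    isotype: str | None = None


@dataclass
class UniqueSequence:
    sequence: str
    mid: str
    fwd_primer: str
    rev_primer: str
    isotype: str
    duplicate_count: int


@dataclass
class StageLog:
    stage: str
    n_in: int = 0
    retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + 1

    def check(self) -> None:
        assert self.n_in == self.retained + sum(self.removed.values())


def mean_quality(qual: str) -> float:
    return float(np.mean([ord(c) - 33 for c in qual]))


def quality_filter(reads: list[Read], min_length: int = 250,
                   min_mean_q: float = 20.0) -> tuple[list[Read], StageLog]:
    """Remove reads shorter than ``min_length`` or with mean Phred below
    ``min_mean_q`` (strictly-less removal on both)."""
    log = StageLog("quality_filter", n_in=len(reads))
    kept = []
    for rid, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"malformed record {rid}: seq/qual length differ")
        if len(seq) < min_length:
            log.drop("length")
        elif mean_quality(qual) < min_mean_q:
            log.drop("quality")
        else:
            kept.append((rid, seq, qual))
    log.retained = len(kept)
    log.check()
    return kept, log


def demux_mid(reads: list[Read], mid_set: list[str]
              ) -> tuple[list[AnnotatedRead], StageLog]:
    """Exact-match MID assignment at the 5' end, with exact-match excision at
    the 3' end where present; reads without an exact 5' MID are removed."""
    if len(set(mid_set)) != len(mid_set):
        raise ValueError("duplicate MIDs in set")
    log = StageLog("demux_mid", n_in=len(reads))
    out = []
    for rid, seq, _ in reads:
        mid = next((m for m in mid_set if seq.startswith(m)), None)
        if mid is None:
            log.drop("no_mid")
            continue
        trimmed = seq[len(mid):]
        for m in mid_set:  # 3' MID (any sample's) excised when present
            if trimmed.endswith(m):
                trimmed = trimmed[: -len(m)]
                break
        out.append(AnnotatedRead(rid, trimmed, mid))
    log.retained = len(out)
    log.check()
    return out, log


def _mismatch_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(b)


def match_primers(reads: list[AnnotatedRead],
                  fwd_primers: dict[str, str],
                  rev_primers: dict[str, str],
                  max_error: float = 0.2
                  ) -> tuple[list[AnnotatedRead], StageLog]:
    """Match primers at both read ends with mismatch fraction <= max_error
    (inclusive); mask the forward-primer region with Ns (length preserved),
    trim the reverse-primer region, and infer isotype from the reverse
    primer id.

    Comparison is ungapped at the expected offset (read start / read end).
    """
    if not fwd_primers or not rev_primers:
        raise ValueError("primer sets must be non-empty")
    log = StageLog("match_primers", n_in=len(reads))
    out = []
    for r in reads:
        best_f = min(((pid, _mismatch_fraction(r.sequence[: len(p)], p))
                      for pid, p in fwd_primers.items() if len(r.sequence) >= len(p)),
                     key=lambda t: t[1], default=None)
        if best_f is None or best_f[1] > max_error:
            log.drop("fwd_primer")
            continue
        best_r = min(((pid, _mismatch_fraction(r.sequence[-len(p):], p))
                      for pid, p in rev_primers.items() if len(r.sequence) >= len(p)),
                     key=lambda t: t[1], default=None)
        if best_r is None or best_r[1] > max_error:
            log.drop("rev_primer")
            continue
        fp = fwd_primers[best_f[0]]
        rp = rev_primers[best_r[0]]
        masked = "N" * len(fp) + r.sequence[len(fp): -len(rp)]
        out.append(AnnotatedRead(r.read_id, masked, r.mid, best_f[0],
                                 best_r[0], isotype=best_r[0]))
    log.retained = len(out)
    log.check()
    return out, log


def collapse_duplicates(reads: list[AnnotatedRead]) -> list[UniqueSequence]:
    """Collapse reads identical in (sequence, MID, forward primer, reverse
    primer) into unique sequences carrying a duplicate count."""
    groups: dict[tuple, UniqueSequence] = {}
    for r in reads:
        key = (r.sequence, r.mid, r.fwd_primer, r.rev_primer)
        if key in groups:
            groups[key].duplicate_count += 1
        else:
            groups[key] = UniqueSequence(r.sequence, r.mid, r.fwd_primer or "",
                                         r.rev_primer or "", r.isotype or "",
                                         1)
    return list(groups.values())


def functionality_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, StageLog]:
    """Retain functional, MID-consistent rearrangements (reads whose 5'/3'
    MIDs disagree are treated as chimeric artefacts)."""
    for col in ("functional", "mid_consistent"):
        if col not in records.columns:
            raise ValueError(f"missing required flag column {col!r}")
    log = StageLog("functionality_filter", n_in=len(records))
    nonfunc = ~records["functional"].astype(bool)
    midbad = records["functional"].astype(bool) & ~records["mid_consistent"].astype(bool)
    keep = records["functional"].astype(bool) & records["mid_consistent"].astype(bool)
    log.removed = {"non_functional": int(nonfunc.sum()),
                   "mid_mismatch": int(midbad.sum())}
    log.retained = int(keep.sum())
    log.check()
    return records.loc[keep].reset_index(drop=True), log


def chimera_window_filter(sequence: str, germline: str, window: int = 10,
                          max_mut: int = 5) -> bool:
    """True (keep) unless some full-length ``window`` holds more than
    ``max_mut`` mismatches against the position-aligned germline.

    N positions (in either string) never count as mismatches.  Windows
    shorter than ``window`` at the trailing end are not evaluated.
    """
    if len(sequence) != len(germline):
        raise ValueError("sequence/germline length mismatch")
    mism = np.array([a != b and a != "N" and b != "N"
                     for a, b in zip(sequence, germline)], dtype=int)
    if len(mism) < window:
        return True
    counts = np.convolve(mism, np.ones(window, dtype=int), mode="valid")
    return bool(counts.max() <= max_mut)


def apply_chimera_filter(records: pd.DataFrame, window: int = 10,
                         max_mut: int = 5) -> tuple[pd.DataFrame, StageLog]:
    log = StageLog("chimera_window_filter", n_in=len(records))
    keep = records.apply(
        lambda r: chimera_window_filter(r["sequence"],
                                        r["germline_alignment"],
                                        window, max_mut), axis=1)
    log.removed = {"chimera_window": int((~keep).sum())}
    log.retained = int(keep.sum())
    log.check()
    return records.loc[keep].reset_index(drop=True), log


def mutation_frequency(sequence: str, germline: str) -> tuple[int, float]:
    """Mutation count and frequency against the aligned germline.

    Positions where either string is N (masked primer region, junction
    N-region) are excluded from both the count and the evaluated length.
    """
    if len(sequence) != len(germline):
        raise ValueError("sequence/germline length mismatch")
    pairs = [(a, b) for a, b in zip(sequence, germline)
             if a != "N" and b != "N"]
    if not pairs:
        raise ValueError("zero evaluated length")
    count = sum(a != b for a, b in pairs)
    return count, count / len(pairs)


def annotate_mutations(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    stats = [mutation_frequency(s, g) for s, g in
             zip(out["sequence"], out["germline_alignment"])]
    out["mutation_count"] = [c for c, _ in stats]
    out["mutation_freq"] = [f for _, f in stats]
    return out
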