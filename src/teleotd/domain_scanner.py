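"""Profile construction and domain scanning for PRDM9 architectures.

The scanner covers the decision logic of a PRDM9 survey: build a
position-specific log-odds profile from a (consensus-score filtered)
alignment, slide it over protein sequences or six-frame genome
translations, detect C2H2 zinc fingers and their tandem arrays, pick a
canonical transcript per gene, and threshold best scores into
presence/absence calls.

The profile here is a log-odds matrix (PSSM), not a full HMM: the windowed
score-plus-threshold contract of an HMM domain search is reproduced while
the numerics are the simpler position-independent log-odds. Thresholds are
therefore configuration, with the conventional defaults: aKRAB against
six-frame genome translations, present at score >= 30; aKRAB against
proteins, absent <= 20 / present >= 50 / uncertain between; extended
PR-SET (ePR-SET), present at >= 180; consensus-score alignment filter
at 250.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_THRESHOLDS",
    "ProfileModel",
    "DomainHit",
    "ProteinArchitecture",
    "PresenceCall",
    "PeptideSegment",
    "Frame",
    "consensus_scores",
    "filter_alignment",
    "build_profile",
    "scan_peptides",
    "six_frame_translate",
    "detect_zn_fingers",
    "select_canonical",
    "call_presence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = {"-", "."}

DEFAULT_THRESHOLDS: dict[str, dict[str, float]] = {
    "akrab": {"genome": 30.0, "protein_absent": 20.0, "protein_present": 50.0},
    "eprset": {"protein": 180.0, "genome": 180.0},
}

#: Simplified C2H2 zinc-finger motif: C-x(2,4)-C-x(11,13)-H-x(3,5)-H.
ZN_FINGER_PATTERN = re.compile(r"C.{2,4}C.{11,13}H.{3,5}H")


Alignment = Sequence[tuple[str, str]]


def _rows(alignment) -> list[tuple[str, str]]:
    """Normalise an alignment to [(id, upper-case row)]; rows must be equal
    length. Accepts [(id, seq)] pairs or Biopython SeqRecord iterables."""
    rows: list[tuple[str, str]] = []
    for item in alignment:
        if isinstance(item, tuple):
            rid, seq = item
        else:  # SeqRecord-like
            rid, seq = item.id, str(item.seq)
        rows.append((rid, seq.upper()))
    if not rows:
        raise ValueError("empty alignment")
    length = len(rows[0][1])
    if any(len(seq) != length for _, seq in rows):
        raise ValueError("ragged alignment: rows differ in length")
    return rows


# ---------------------------------------------------------------------------
# Consensus scores and the alignment filter
# ---------------------------------------------------------------------------

def consensus_scores(alignment: Alignment) -> dict[str, float]:
    """Per-sequence consensus score over an alignment.

    The score of a row is the sum, over columns, of how many rows (itself
    included) carry the same residue in that column; gap positions
    contribute zero. Permutation-invariant over rows.
    """
    rows = _rows(alignment)
    length = len(rows[0][1])
    col_counts: list[Counter] = []
    for j in range(length):
        c: Counter = Counter()
        for _, seq in rows:
            ch = seq[j]
            if ch not in GAP_CHARS:
                c[ch] += 1
        col_counts.append(c)
    scores: dict[str, float] = {}
    for rid, seq in rows:
        s = 0
        for j, ch in enumerate(seq):
            if ch not in GAP_CHARS:
                s += col_counts[j][ch]
        scores[rid] = float(s)
    return scores


def filter_alignment(
    alignment: Alignment, threshold: float = 250.0
) -> list[tuple[str, str]]:
    """Drop rows whose consensus score is below the threshold.

    A single pass: survivors keep their original columns (no re-alignment).
    Removed ids are logged; removing every row raises.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = _rows(alignment)
    scores = consensus_scores(rows)
    kept = [(rid, seq) for rid, seq in rows if scores[rid] >= threshold]
    removed = [rid for rid, _ in rows if scores[rid] < threshold]
    if removed:
        log.info("consensus filter removed %d row(s): %s",
                 len(removed), ", ".join(removed))
    if not kept:
        raise ValueError(
            f"consensus filter at {threshold} removed every row"
        )
    return kept


# ---------------------------------------------------------------------------
# Profile model and scanning
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Column-wise log-odds weights (bits) against background frequencies.

    ``weights[j, r]`` scores residue ``r`` (indexed by :data:`AMINO_ACIDS`)
    at model column ``j``; unknown residues score zero (background odds).
    Alignment columns with more than 50% gaps are dropped from the model.
    """

    name: str
    weights: np.ndarray          # (length, 20)
    background: np.ndarray       # (20,)
    pseudocount: float
    kept_columns: tuple[int, ...]  # source-alignment column indices

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.weights, axis=1))

    def max_score(self) -> float:
        return float(np.max(self.weights, axis=1).sum())


@dataclass(frozen=True)
class DomainHit:
    sequence_id: str
    model: str
    start: int   # 1-based inclusive residue coordinates
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start must be <= end")


@dataclass
class ProteinArchitecture:
    """Ordered domain content of one protein."""

    protein_id: str
    hits: list[DomainHit]
    has_akrab: bool
    prset_present: bool
    n_zn_fingers: int
    zn_arrays: list[tuple[int, int]]  # (first finger index, n fingers)


@dataclass(frozen=True)
class PresenceCall:
    model: str
    best_score: float
    call: str                      # present | absent | uncertain
    thresholds: tuple[float, ...]


def build_profile(
    alignment: Alignment,
    name: str = "profile",
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> ProfileModel:
    """Log-odds profile from a (filtered) alignment.

    weight(col, r) = log2(((count + pc * bg_r) / (n_rows + pc)) / bg_r),
    the standard pseudocount-smoothed log-odds. Columns with more than 50%
    gaps are dropped. Background defaults to uniform 1/20.
    """
    rows = _rows(alignment)
    n = len(rows)
    bg = (
        np.full(20, 1 / 20.0)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    length = len(rows[0][1])
    cols: list[np.ndarray] = []
    kept: list[int] = []
    for j in range(length):
        counts = np.zeros(20)
        gaps = 0
        for _, seq in rows:
            ch = seq[j]
            if ch in GAP_CHARS:
                gaps += 1
            elif ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        if gaps > n / 2:
            continue
        w = np.log2(((counts + pseudocount * bg) / (n + pseudocount)) / bg)
        cols.append(w)
        kept.append(j)
    if not cols:
        raise ValueError("no columns survive the gap filter")
    return ProfileModel(
        name=name,
        weights=np.vstack(cols),
        background=bg,
        pseudocount=pseudocount,
        kept_columns=tuple(kept),
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq.upper()],
                    dtype=np.int64)


def window_scores(profile: ProfileModel, seq: str) -> np.ndarray:
    """Score of every profile-length window of ``seq`` (empty if too short).

    Unknown residues contribute zero (background odds).
    """
    idx = _encode(seq)
    L, n = profile.length, idx.size
    if n < L:
        return np.empty(0)
    padded = np.vstack([profile.weights.T, np.zeros((1, L))])  # row -1 = 0
    scores = np.zeros(n - L + 1)
    for j in range(L):
        scores += padded[idx[j : n - L + 1 + j], j]
    return scores


def scan_peptides(
    profile: ProfileModel,
    seq: str,
    sequence_id: str = "seq",
    threshold: float = 0.0,
) -> list[DomainHit]:
    """Slide the profile over all windows and report non-overlapping hits.

    Hits scoring at least ``threshold`` are selected greedily by descending
    score. When no window reaches the threshold the single best window is
    still reported (with its sub-threshold score) so presence calls can be
    calibrated; a sequence shorter than the profile yields no hits.
    """
    scores = window_scores(profile, seq)
    if scores.size == 0:
        return []
    L = profile.length
    order = np.argsort(scores, kind="stable")[::-1]
    taken = np.zeros(scores.size, dtype=bool)
    hits: list[DomainHit] = []
    for i in order:
        if scores[i] < threshold:
            break
        if taken[max(0, i - L + 1): i + L].any():
            continue
        taken[i] = True
        hits.append(
            DomainHit(sequence_id, profile.name, int(i) + 1,
                      int(i) + L, float(scores[i]))
        )
    if not hits:
        best = int(order[0])
        hits.append(
            DomainHit(sequence_id, profile.name, best + 1,
                      best + L, float(scores[best]))
        )
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideSegment:
    """A stop-free peptide stretch of one reading frame.

    ``genomic_start`` is the 1-based coordinate (on the forward strand's
    numbering) of the first base of the segment's first codon *as read on
    its strand*; for reverse frames that is the higher coordinate of the
    codon.
    """

    peptide: str
    genomic_start: int
    frame: int  # +1..+3, -1..-3

    def codon_start(self, residue_index: int) -> int:
        """Genomic coordinate of the first base of codon ``residue_index``
        (0-based into :attr:`peptide`)."""
        if self.frame > 0:
            return self.genomic_start + 3 * residue_index
        return self.genomic_start - 3 * residue_index


@dataclass
class Frame:
    frame: int
    segments: list[PeptideSegment]


def six_frame_translate(dna: str) -> list[Frame]:
    """Translate all six frames, splitting at stop codons.

    Alphabet ACGTN (N translates through X via the standard code). Scanning
    operates within the returned stop-free segments, whose genomic offsets
    map every residue back to its codon start.
    """
    dna = dna.upper().replace("U", "T")
    if not dna:
        raise ValueError("empty input sequence")
    if re.search(r"[^ACGTN]", dna):
        raise ValueError("alphabet must be ACGTN")
    n = len(dna)
    rc = str(Seq(dna).reverse_complement())
    frames: list[Frame] = []
    for strand, template in ((1, dna), (-1, rc)):
        for f in range(3):
            usable = (n - f) // 3 * 3
            if usable <= 0:
                frames.append(Frame(strand * (f + 1), []))
                continue
            pep = str(Seq(template[f : f + usable]).translate())
            segments: list[PeptideSegment] = []
            start = 0
            for chunk in pep.split("*"):
                if chunk:
                    # position of codon `start` in the template
                    tpos = f + 3 * start
                    genomic = tpos + 1 if strand == 1 else n - tpos
                    segments.append(
                        PeptideSegment(chunk, genomic, strand * (f + 1))
                    )
                start += len(chunk) + 1
            frames.append(Frame(strand * (f + 1), segments))
    return frames


# ---------------------------------------------------------------------------
# Zinc fingers, canonical transcripts, presence calls
# ---------------------------------------------------------------------------

def detect_zn_fingers(
    seq: str, array_gap: int = 15
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """C2H2 fingers and their tandem arrays.

    Fingers match the simplified motif C-x(2,4)-C-x(11,13)-H-x(3,5)-H,
    taken non-overlapping left to right; consecutive fingers separated by
    at most ``array_gap`` residues belong to one array. Returns
    ``(fingers, arrays)`` with fingers as 1-based (start, end) pairs and
    arrays as (first finger index 1-based, finger count).
    """
    fingers = [
        (m.start() + 1, m.end())
        for m in ZN_FINGER_PATTERN.finditer(seq.upper())
    ]
    arrays: list[tuple[int, int]] = []
    for i, (s, _e) in enumerate(fingers):
        if arrays and s - fingers[i - 1][1] - 1 <= array_gap:
            first, count = arrays[-1]
            arrays[-1] = (first, count + 1)
        else:
            arrays.append((i + 1, 1))
    return fingers, arrays


def select_canonical(
    architectures: Mapping[str, Sequence[DomainHit]]
) -> str:
    """Pick the canonical transcript of one gene.

    Largest number of distinct domain models; ties broken by largest summed
    hit length, then by lexicographically smallest transcript id.
    """
    if not architectures:
        raise ValueError("no transcripts given")

    def key(tid: str):
        hits = architectures[tid]
        n_models = len({h.model for h in hits})
        total = sum(h.end - h.start + 1 for h in hits)
        return (-n_models, -total, tid)

    return min(architectures, key=key)


def call_presence(
    best_score: float,
    model: str,
    context: str,
    thresholds: Mapping[str, Mapping[str, float]] | None = None,
) -> PresenceCall:
    """Threshold a best domain score into present / absent / uncertain.

    aKRAB against genome translations: present iff score >= 30. aKRAB
    against proteins: absent <= 20, present >= 50, uncertain in between.
    ePR-SET: present iff score >= 180. All boundaries come from
    ``thresholds`` (default :data:`DEFAULT_THRESHOLDS`).
    """
    if not np.isfinite(best_score):
        raise ValueError("score must be finite")
    if context not in {"protein", "genome"}:
        raise ValueError(f"unknown context {context!r}")
    table = thresholds or DEFAULT_THRESHOLDS
    if model not in table:
        raise ValueError(f"unknown model {model!r}")
    t = table[model]
    if model == "akrab" and context == "protein":
        lo, hi = t["protein_absent"], t["protein_present"]
        if best_score <= lo:
            call = "absent"
        elif best_score >= hi:
            call = "present"
        else:
            call = "uncertain"
        return PresenceCall(model, float(best_score), call, (lo, hi))
    cut = t["genome"] if context == "genome" else t.get("protein", t["genome"])
    call = "present" if best_score >= cut else "absent"
    return PresenceCall(model, float(best_score), call, (cut,))


def protein_architecture(
    protein_id: str,
    seq: str,
    akrab_profile: ProfileModel | None = None,
    prset_profile: ProfileModel | None = None,
    thresholds: Mapping[str, Mapping[str, float]] | None = None,
    array_gap: int = 15,
) -> ProteinArchitecture:
    """Scan one protein with the given profiles and summarise its domains."""
    hits: list[DomainHit] = []
    has_akrab = False
    prset_present = False
    if akrab_profile is not None:
        ak_hits = scan_peptides(akrab_profile, seq, protein_id)
        if ak_hits:
            best = max(h.score for h in ak_hits)
            has_akrab = (
                call_presence(best, "akrab", "protein", thresholds).call
                == "present"
            )
            hits.extend(ak_hits)
    if prset_profile is not None:
        ps_hits = scan_peptides(prset_profile, seq, protein_id)
        if ps_hits:
            best = max(h.score for h in ps_hits)
            prset_present = (
                call_presence(best, "eprset", "protein", thresholds).call
                == "present"
            )
            hits.extend(ps_hits)
    fingers, arrays = detect_zn_fingers(seq, array_gap=array_gap)
    hits.sort(key=lambda h: h.start)
    return ProteinArchitecture(
        protein_id=protein_id,
        hits=hits,
        has_akrab=has_akrab,
        prset_present=prset_present,
        n_zn_fingers=len(fingers),
        zn_arrays=arrays,
    )
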