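"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage (intron extraction, distribution classification,
domain scanning, distance trees, loss inference) can be exercised without
downloading a genome: this module emits GFF3 + FASTA annotations whose
intron sizes follow a controllable log2-space mixture, protein FASTA sets
with planted aKRAB / PR-SET / zinc-finger segments, and labelled phylogenies
with planted domain-loss events.

Intron sizes are realized in log2 space and rounded to integer bp, matching
how the distributions are analysed; a minimum size (``floor``) is enforced
by rejection resampling rather than clipping so no spurious spike appears
at the floor.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import norm

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "AnnotationSpec",
    "SyntheticAnnotation",
    "Segment",
    "ArchitectureSpec",
    "ProteinSet",
    "LossScenario",
    "InfeasibleAntimodeError",
    "ChromosomeOverflowError",
    "solve_mixture_weight",
    "sample_intron_sizes",
    "generate_annotation",
    "generate_protein_set",
    "plant_losses",
    "teleost_fixtures",
    "teleost_mixture",
    "vertebrate_mixture",
    "AMINO_ACIDS",
    "ZN_FINGER_UNIT",
    "SEGMENT_TOKEN",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One canonical C2H2 unit matching C-x(2)-C-x(12)-H-x(3)-H.
ZN_FINGER_UNIT = "CPYCGKSFSQKSNLYVH" + "QRT" + "H"
#: Linker placed between consecutive fingers of one array (gap 5 <= 15).
ZN_FINGER_LINKER = "TGEKP"

#: Reserved FASTA-header token carrying planted segment coordinates.
SEGMENT_TOKEN = "segments="


class InfeasibleAntimodeError(ValueError):
    """No mixture weight in (0, 1) places the interior minimum at the target."""


class ChromosomeOverflowError(ValueError):
    """Generated features would exceed the declared chromosome length."""


# ---------------------------------------------------------------------------
# Intron-size mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    """One normal component in log2-bp space; ``weight=None`` marks it free."""

    weight: float | None
    mean: float
    sd: float


@dataclass(frozen=True)
class MixtureSpec:
    """Log2-space normal mixture of intron sizes.

    Either all component weights are given and sum to 1, or
    ``antimode_target`` is set and the weights are left unset (``None``):
    with the sum-to-one constraint a two-component mixture then has exactly
    one free weight, solved so the interior density minimum falls at the
    target.
    """

    components: tuple[MixtureComponent, ...]
    floor: int = 60
    antimode_target: float | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        if any(c.sd < 0 for c in self.components):
            raise ValueError("component sds must be >= 0")
        if self.floor < 1:
            raise ValueError("floor must be >= 1 bp")
        free = [c for c in self.components if c.weight is None]
        if self.antimode_target is None:
            if free:
                raise ValueError("free weight requires antimode_target")
            total = sum(c.weight for c in self.components)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"weights sum to {total}, expected 1")
        else:
            if len(self.components) != 2 or len(free) != 2:
                raise ValueError(
                    "antimode_target solving requires two components with "
                    "unset weights (one effective free weight under the "
                    "sum-to-one constraint)"
                )

    @property
    def is_solved(self) -> bool:
        return all(c.weight is not None for c in self.components)

    def solved(self) -> "MixtureSpec":
        """Resolve the free weight so the antimode sits at the target."""
        if self.is_solved:
            return self
        if len(self.components) != 2:
            raise ValueError("weight solving is defined for two components")
        lo, hi = sorted(self.components, key=lambda c: c.mean)
        w1 = solve_mixture_weight(
            lo.mean, lo.sd, hi.mean, hi.sd, self.antimode_target
        )
        comps = (
            replace(lo, weight=w1),
            replace(hi, weight=1.0 - w1),
        )
        return MixtureSpec(comps, floor=self.floor, antimode_target=None)

    def density(self, x: np.ndarray | float) -> np.ndarray:
        """Mixture density in log2-bp space (weights must be resolved)."""
        if not self.is_solved:
            raise ValueError("unsolved mixture; call .solved() first")
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.weight * norm.pdf(x, loc=c.mean, scale=c.sd)
        return out


def solve_mixture_weight(
    m1: float, s1: float, m2: float, s2: float, antimode_target: float
) -> float:
    """Weight of the low component placing the interior minimum at the target.

    For a two-component normal mixture f = w g1 + (1-w) g2 in log2 space the
    stationarity condition f'(t) = 0 is linear in w, so the root is exact:
    w = g2'(t) / (g2'(t) - g1'(t)). The solution is verified to be the
    interior *minimum* between the two modes on a dense grid; targets for
    which no weight in (0, 1) achieves that raise
    :class:`InfeasibleAntimodeError`.
    """
    if not (m1 < antimode_target < m2):
        raise InfeasibleAntimodeError(
            f"target {antimode_target} must lie strictly between the means "
            f"({m1}, {m2})"
        )
    t = antimode_target
    d1 = -(t - m1) / s1**2 * norm.pdf(t, m1, s1)
    d2 = -(t - m2) / s2**2 * norm.pdf(t, m2, s2)
    if d2 == d1:
        raise InfeasibleAntimodeError("degenerate derivative; no unique root")
    w1 = d2 / (d2 - d1)
    if not (0.0 < w1 < 1.0):
        raise InfeasibleAntimodeError(
            f"solved weight {w1:.4g} outside (0, 1); target infeasible"
        )
    spec = MixtureSpec(
        (MixtureComponent(w1, m1, s1), MixtureComponent(1.0 - w1, m2, s2)),
        floor=1,
    )
    grid = np.linspace(m1, m2, 4001)
    interior = grid[np.argmin(spec.density(grid))]
    if abs(interior - t) > 0.01:
        raise InfeasibleAntimodeError(
            f"stationary point at {t} is not the interior minimum "
            f"(minimum found at {interior:.3f})"
        )
    return float(w1)


def teleost_mixture(floor: int = 60) -> MixtureSpec:
    """Default TD-shaped mixture: dominant short peak, antimode at 2^8 bp."""
    return MixtureSpec(
        (
            MixtureComponent(None, 6.5, 0.35),
            MixtureComponent(None, 10.0, 1.2),
        ),
        floor=floor,
        antimode_target=8.0,
    ).solved()


def vertebrate_mixture(floor: int = 60) -> MixtureSpec:
    """Default non-TD mixture: small short peak, antimode at 2^7.25 bp."""
    return MixtureSpec(
        (
            MixtureComponent(None, 6.5, 0.3),
            MixtureComponent(None, 9.75, 1.25),
        ),
        floor=floor,
        antimode_target=7.25,
    ).solved()


def sample_intron_sizes(
    spec: MixtureSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer intron sizes (bp) from the log2-space mixture.

    Sizes are 2**x rounded to the nearest integer for x drawn from the
    mixture; draws that round below ``spec.floor`` are rejected and redrawn.
    Deterministic for a fixed integer seed.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not spec.is_solved:
        raise ValueError("unsolved mixture; call .solved() first")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    weights = np.array([c.weight for c in spec.components])
    means = np.array([c.mean for c in spec.components])
    sds = np.array([c.sd for c in spec.components])
    out = np.empty(n, dtype=np.int64)
    todo = n
    while todo:
        comp = rng.choice(len(weights), size=todo, p=weights)
        x = rng.normal(means[comp], sds[comp])
        sizes = np.rint(np.exp2(x)).astype(np.int64)
        keep = sizes >= spec.floor
        k = int(keep.sum())
        out[n - todo : n - todo + k] = sizes[keep]
        todo -= k
    return out


# ---------------------------------------------------------------------------
# Annotation generator (GFF3 + genome FASTA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationSpec:
    """Shape of a synthetic annotation: gene/transcript/exon counts + introns."""

    n_genes: int
    intron_model: MixtureSpec
    transcripts_per_gene: tuple[int, int] = (1, 1)
    exons_per_transcript: tuple[int, int] = (2, 8)
    exon_size: tuple[int, int] = (80, 300)
    seqid_count: int = 4
    intergenic: tuple[int, int] = (200, 1000)
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("transcripts_per_gene", "exons_per_transcript",
                     "exon_size", "intergenic"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_genes < 1 or self.seqid_count < 1:
            raise ValueError("n_genes and seqid_count must be >= 1")


@dataclass
class SyntheticAnnotation:
    """Generated annotation bundle with the planted ground truth."""

    gff_text: str
    fasta_text: str
    intron_sizes: list[int]       # in sampling order, one entry per intron
    gene_introns: dict[str, list[int]]  # gene id -> its intron sizes


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def generate_annotation(spec: AnnotationSpec, seed: int) -> SyntheticAnnotation:
    """Emit GFF3 + FASTA such that re-extracting introns recovers the
    sampled sizes exactly.

    All transcripts of one gene share the same exon structure (so
    isoform-deduplication behaviour is testable); strands alternate by gene
    but never change genomic coordinates.
    """
    if not spec.intron_model.is_solved:
        raise ValueError("intron_model has an unsolved free weight")
    rng = np.random.default_rng(seed)
    cursors = {f"chr{i + 1}": 0 for i in range(spec.seqid_count)}
    seqids = list(cursors)
    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    intron_sizes: list[int] = []
    gene_introns: dict[str, list[int]] = {}

    for g in range(spec.n_genes):
        seqid = seqids[g % len(seqids)]
        strand = "+" if g % 2 == 0 else "-"
        n_tr = int(rng.integers(*spec.transcripts_per_gene, endpoint=True))
        n_ex = int(rng.integers(*spec.exons_per_transcript, endpoint=True))
        ex_sizes = rng.integers(*spec.exon_size, size=n_ex, endpoint=True)
        if n_ex > 1:
            sizes = sample_intron_sizes(spec.intron_model, n_ex - 1, rng)
        else:
            sizes = np.empty(0, dtype=np.int64)
        gap = int(rng.integers(*spec.intergenic, endpoint=True))
        start = cursors[seqid] + gap + 1
        exons: list[tuple[int, int]] = []
        pos = start
        for i, es in enumerate(ex_sizes):
            exons.append((pos, pos + int(es) - 1))
            pos += int(es)
            if i < n_ex - 1:
                pos += int(sizes[i])
        end = exons[-1][1]
        if spec.chrom_length is not None and end > spec.chrom_length:
            raise ChromosomeOverflowError(
                f"gene {g} would end at {end} > chrom_length "
                f"{spec.chrom_length} on {seqid}"
            )
        cursors[seqid] = end
        gid = f"gene{g:05d}"
        intron_sizes.extend(int(s) for s in sizes)
        gene_introns[gid] = [int(s) for s in sizes]
        gff.write(
            f"{seqid}\tteleotd\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={gid}\n"
        )
        for t in range(n_tr):
            tid = f"{gid}.t{t + 1}"
            gff.write(
                f"{seqid}\tteleotd\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            for k, (es, ee) in enumerate(exons):
                gff.write(
                    f"{seqid}\tteleotd\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={tid}.e{k + 1};Parent={tid}\n"
                )

    fasta = io.StringIO()
    for seqid in seqids:
        length = max(cursors[seqid] + 100, 200)
        bases = rng.choice(list("ACGT"), size=length)
        fasta.write(f">{seqid}\n{_wrap(''.join(bases))}\n")
    return SyntheticAnnotation(
        gff_text=gff.getvalue(),
        fasta_text=fasta.getvalue(),
        intron_sizes=intron_sizes,
        gene_introns=gene_introns,
    )


# ---------------------------------------------------------------------------
# Protein families with planted domain segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One architecture segment: kind, per-copy length (residues), copies."""

    kind: str                     # akrab | prset | znfinger_array | linker
    length: int
    copies: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"akrab", "prset", "znfinger_array", "linker"}:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length <= 0 or self.copies < 1:
            raise ValueError("segment length and copies must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered domain layout of a synthetic protein family.

    ``consensus`` maps a segment kind to its literal consensus sequence; a
    kind without an entry gets a deterministic random consensus (zinc-finger
    arrays always use the canonical C2H2 unit so the planted fingers match
    the detection pattern).
    """

    segments: tuple[Segment, ...]
    substitution_rate: float = 0.0
    consensus: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        for seg in self.segments:
            src = self.consensus.get(seg.kind)
            if src is not None and seg.kind != "znfinger_array" \
                    and len(src) < seg.length:
                raise ValueError(
                    f"consensus for {seg.kind!r} shorter than declared "
                    f"length {seg.length}"
                )


@dataclass
class ProteinSet:
    """Generated proteins plus the planted truth used by test oracles."""

    records: list[tuple[str, str]]            # (id, sequence)
    consensus: dict[str, str]                 # kind -> consensus used
    truth: dict[str, list[tuple[str, int, int]]]  # id -> (kind, start, end) 1-based

    @property
    def fasta_text(self) -> str:
        out = io.StringIO()
        for pid, seq in self.records:
            coords = ";".join(
                f"{kind}:{s}-{e}" for kind, s, e in self.truth[pid]
            )
            out.write(f">{pid} {SEGMENT_TOKEN}{coords}\n{_wrap(seq)}\n")
        return out.getvalue()


def parse_segment_header(header: str) -> list[tuple[str, int, int]]:
    """Recover planted (kind, start, end) coordinates from a FASTA header."""
    m = re.search(rf"{SEGMENT_TOKEN}(\S+)", header)
    if not m:
        return []
    out = []
    for part in m.group(1).split(";"):
        kind, span = part.split(":")
        s, e = span.split("-")
        out.append((kind, int(s), int(e)))
    return out


def _segment_consensus(seg: Segment, spec: ArchitectureSpec,
                       rng: np.random.Generator) -> str:
    if seg.kind == "znfinger_array":
        unit = spec.consensus.get("znfinger_array", ZN_FINGER_UNIT)
        return ZN_FINGER_LINKER.join([unit] * seg.copies)
    src = spec.consensus.get(seg.kind)
    if src is None:
        src = "".join(rng.choice(list(AMINO_ACIDS), size=seg.length))
    return src[: seg.length] * seg.copies


def generate_protein_set(
    arch: ArchitectureSpec, n: int, seed: int
) -> ProteinSet:
    """Concatenate segment consensi, mutate i.i.d., record planted truth.

    Each position mutates with probability ``substitution_rate`` to a
    uniformly chosen *different* residue. True segment coordinates ride in
    the FASTA headers after the reserved ``segments=`` token so oracles need
    no side files.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    consensus_map: dict[str, str] = {}
    parts: list[tuple[str, str]] = []
    for seg in arch.segments:
        cons = _segment_consensus(seg, arch, rng)
        consensus_map.setdefault(seg.kind, cons)
        parts.append((seg.kind, cons))
    records: list[tuple[str, str]] = []
    truth: dict[str, list[tuple[str, int, int]]] = {}
    aa = np.array(list(AMINO_ACIDS))
    for i in range(n):
        pid = f"prot{i:04d}"
        seq_parts: list[str] = []
        coords: list[tuple[str, int, int]] = []
        pos = 1
        for kind, cons in parts:
            coords.append((kind, pos, pos + len(cons) - 1))
            seq_parts.append(cons)
            pos += len(cons)
        seq = np.array(list("".join(seq_parts)))
        if arch.substitution_rate > 0:
            mask = rng.random(seq.size) < arch.substitution_rate
            for j in np.flatnonzero(mask):
                choices = aa[aa != seq[j]]
                seq[j] = rng.choice(choices)
        records.append((pid, "".join(seq)))
        truth[pid] = coords
    return ProteinSet(records=records, consensus=consensus_map, truth=truth)


# ---------------------------------------------------------------------------
# Planted loss scenarios on trees
# ---------------------------------------------------------------------------

@dataclass
class LossScenario:
    """A tree with planted loss branches and the induced leaf labels."""

    tree: dendropy.Tree
    loss_clades: list[frozenset[str]]   # descendant leaf-label sets
    labels: dict[str, str]              # leaf label -> present | absent


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def plant_losses(tree: dendropy.Tree, k: int, seed: int) -> LossScenario:
    """Mark ``k`` non-nested branches as losses; descendants become absent.

    No selected branch is ancestral to another; deterministic for a fixed
    seed. Raises ``ValueError`` when the tree admits no such selection.
    """
    tree = tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node]
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if k > n_leaves:
        raise ValueError(
            f"cannot select {k} pairwise non-nested branches on this tree"
        )
    chosen_sets: list[frozenset[str]] = []
    # greedy selection over a random order can dead-end (early picks may
    # cover the whole leaf set); retry with fresh shuffles, deterministically
    for _attempt in range(200 if k else 0):
        chosen_sets = []
        for idx in rng.permutation(len(nodes)):
            nd = nodes[idx]
            ls = _leafset(nd)
            if len(ls) == n_leaves:
                continue  # would label every leaf absent
            if any(ls <= cs or cs <= ls for cs in chosen_sets):
                continue
            chosen_sets.append(ls)
            if len(chosen_sets) == k:
                break
        if len(chosen_sets) == k:
            break
    if len(chosen_sets) != k:
        raise ValueError(
            f"cannot select {k} pairwise non-nested branches on this tree"
        )
    absent = set().union(*chosen_sets) if chosen_sets else set()
    labels = {
        lf.taxon.label: ("absent" if lf.taxon.label in absent else "present")
        for lf in tree.leaf_node_iter()
    }
    return LossScenario(tree=tree, loss_clades=chosen_sets, labels=labels)


# ---------------------------------------------------------------------------
# Order-level teleost fixture tree with aKRAB / TD labels
# ---------------------------------------------------------------------------

#: Rooted order-level teleost topology, one representative leaf per taxon.
#: Branch lengths are arbitrary positives; inference uses topology only.
_FIXTURE_NEWICK = """(
 Anguilliformes:1,
 (
  (Osteoglossidae:1, Mormyridae:1):1,
  (
   (Denticeps_clupeoides:1, Clupea_harengus:1):1,
   (
    (
     Gonorynchiformes:1,
     (
      Cypriniformes:1,
      (Gymnotiformes:1, (Characiformes:1, Siluriformes:1):1):1
     ):1
    ):1,
    (
     ((Esociformes:1, Salmoniformes:1):1, Osmeriformes:1):1,
     (
      Guentherus_altivela:1,
      (
       Aulopiformes:1,
       (
        Myctophiformes:1,
        (
         (
          Polymixiiformes:1,
          (
           Percopsiformes:1,
           (
            Zeiformes:1,
            (
             Coryphaenoides_rupestris:1,
             (Gadus_morhua:1, Merluccius_productus:1):1
            ):1
           ):1
          ):1
         ):1,
         (
          Lampriformes:1,
          (Beryciformes:1,
           (Holocentriformes:1, Percomorphaceae:1):1):1
         ):1
        ):1
       ):1
      ):1
     ):1
    ):1
   ):1
  ):1
 ):1
):0;
"""

_AKRAB_ABSENT = {
    "Osteoglossidae",
    "Denticeps_clupeoides",
    "Cypriniformes",
    "Characiformes",
    "Siluriformes",
    "Lampriformes",
    "Beryciformes",
    "Holocentriformes",
    "Percomorphaceae",
    "Zeiformes",
    "Guentherus_altivela",
    "Coryphaenoides_rupestris",
}

_TD_PRESENT = {
    "Denticeps_clupeoides",
    "Cypriniformes",
    "Characiformes",
    "Siluriformes",
    "Lampriformes",
    "Beryciformes",
    "Holocentriformes",
    "Percomorphaceae",
}


def teleost_fixtures() -> tuple[
    dendropy.Tree, dict[str, str], dict[str, str]
]:
    """Order-level teleost tree plus aKRAB and TD leaf-label sets.

    The tree carries one representative leaf per taxon discussed in the
    teleost PRDM9 literature. The aKRAB labels mark the eight lineages where
    the domain is independently absent (Osteoglossidae; *D. clupeoides*;
    Cypriniformes; Characiformes+Siluriformes; Lampriformes+
    Euacanthomorphacea; Zeiformes; *G. altivela*; *C. rupestris*); the TD
    labels mark the four lineages carrying the teleost intron-size
    distribution. Returns ``(tree, akrab_labels, td_labels)`` with label
    values in ``{"present", "absent"}``.
    """
    tree = dendropy.Tree.get(
        data=_FIXTURE_NEWICK, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    akrab = {
        leaf: ("absent" if leaf in _AKRAB_ABSENT else "present")
        for leaf in leaves
    }
    td = {
        leaf: ("present" if leaf in _TD_PRESENT else "absent")
        for leaf in leaves
    }
    return tree, akrab, td
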