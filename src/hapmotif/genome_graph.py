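"""Per-chromosome variation graphs built from a reference plus phased variants.

A :class:`VariationGraph` splits the reference chromosome at variant
boundaries into anchor nodes; each alternate allele becomes a branch node
(deletions become edges that skip reference bases, insertions extra nodes
between anchors), so every variant record forms a bubble anchored on the
reference. Phased sample genotypes are threaded through the bubbles as
explicit haplotype paths. Graphs serialise to and from GFA v1 text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class RefMismatchError(ValueError):
    """A VCF REF allele disagrees with the reference sequence."""


class UnsortedVariantsError(ValueError):
    """Variant records are not sorted by position."""


class PhasingError(ValueError):
    """A non-missing genotype lacks phasing information."""


class WalkError(ValueError):
    """A node list is not a walk over the graph's edges."""


class GFAFormatError(ValueError):
    """Malformed GFA text."""


@dataclass
class VariantRecord:
    """One VCF record with per-sample phased genotypes.

    ``genotypes`` maps sample id to ``(allele0, allele1, phased)``; missing
    genotypes are ``(None, None, False)``.
    """

    chrom: str
    pos: int  # 1-based reference position, as in VCF
    ref_allele: str
    alt_alleles: tuple
    genotypes: dict

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError("REF allele must be nonempty")
        self.alt_alleles = tuple(self.alt_alleles)

    def core(self) -> tuple[int, int, list[str]]:
        """Trim the shared VCF anchor prefix.

        Returns ``(start0, end0, alt_cores)``: the 0-based half-open
        reference interval actually replaced, and the replacement string for
        each alternate allele ('' for a pure deletion).
        """
        alleles = (self.ref_allele,) + self.alt_alleles
        t = 0
        while (
            t < len(self.ref_allele)
            and all(t < len(a) and a[t] == self.ref_allele[t] for a in alleles)
            and not all(len(a) == t + 1 for a in alleles)  # keep SNP cores nonempty
        ):
            t += 1
        start0 = self.pos - 1 + t
        end0 = self.pos - 1 + len(self.ref_allele)
        return start0, end0, [a[t:] for a in self.alt_alleles]


@dataclass
class HaplotypePath:
    sample_id: str
    phase: int  # 0 or 1
    node_ids: list

    @property
    def path_name(self) -> str:
        return f"{self.sample_id}#{self.phase}"


@dataclass
class VariationGraph:
    """Sequence-labelled DAG with a reference path and haplotype paths.

    ``node_span`` maps every node to its reference projection
    ``(start, end, on_ref)``: reference-path nodes carry their true span,
    alternate-branch nodes inherit their bubble's replaced interval (bases
    inside them project to the bubble's left-anchor end, ``start``).
    """

    chrom: str
    nodes: dict = field(default_factory=dict)  # id -> sequence
    edges: set = field(default_factory=set)  # (from_id, to_id)
    ref_path: list = field(default_factory=list)
    haplotype_paths: list = field(default_factory=list)
    node_span: dict = field(default_factory=dict)  # id -> (start, end, on_ref)

    @property
    def ref_offsets(self) -> dict:
        """Reference start coordinate of every reference-path node."""
        return {
            nid: span[0] for nid, span in self.node_span.items() if span[2]
        }

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_paths)

    def reference_length(self) -> int:
        return sum(len(self.nodes[nid]) for nid in self.ref_path)


def _ordered_samples(variants: list[VariantRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for v in variants:
        for s in v.genotypes:
            seen.setdefault(s)
    return list(seen)


def build_graph(
    reference: str,
    variants: list[VariantRecord],
    chrom: str = "chr1",
    samples: list[str] | None = None,
) -> VariationGraph:
    """Build the chromosome variation graph and thread haplotype paths.

    ``variants`` must be position-sorted, on one chromosome, with REF
    alleles matching ``reference``. Records whose replaced interval overlaps
    an earlier record are skipped with a warning (first wins).
    """
    reference = reference.upper()
    if samples is None:
        samples = _ordered_samples(variants)

    graph = VariationGraph(chrom=chrom)
    next_id = [1]

    def new_node(seq: str, span: tuple) -> int:
        nid = next_id[0]
        next_id[0] += 1
        graph.nodes[nid] = seq
        graph.node_span[nid] = span
        return nid

    def connect(tails: list, head: int) -> None:
        for t in tails:
            graph.edges.add((t, head))

    # segments drive haplotype threading: ("anchor", nid) is shared by all
    # paths; ("variant", vr, {allele: nid|None}) selects a branch per allele
    segments: list[tuple] = []
    tails: list[int] = []
    cursor = 0
    last_pos = -1
    for vr in variants:
        if vr.chrom != chrom:
            raise ValueError(
                f"variant on {vr.chrom} passed to graph of {chrom}"
            )
        if vr.pos < last_pos:
            raise UnsortedVariantsError(
                f"variant at {vr.chrom}:{vr.pos} out of order"
            )
        last_pos = vr.pos
        s, e, alt_cores = vr.core()
        if e > len(reference):
            raise RefMismatchError(
                f"variant at {vr.chrom}:{vr.pos} extends past chromosome end"
            )
        if reference[vr.pos - 1 : vr.pos - 1 + len(vr.ref_allele)] != vr.ref_allele.upper():
            raise RefMismatchError(
                f"REF {vr.ref_allele!r} at {vr.chrom}:{vr.pos} does not match "
                "the reference sequence"
            )
        if s < cursor:
            warnings.warn(
                f"variant at {vr.chrom}:{vr.pos} overlaps a previous record; skipped",
                stacklevel=2,
            )
            continue
        for gt in vr.genotypes.values():
            a, b, phased = gt
            if a is None or b is None:
                continue
            if not phased and a != b:
                raise PhasingError(
                    f"unphased heterozygous genotype at {vr.chrom}:{vr.pos}"
                )
            if not (0 <= a <= len(alt_cores)) or not (0 <= b <= len(alt_cores)):
                raise ValueError(
                    f"allele index out of range at {vr.chrom}:{vr.pos}"
                )

        if s > cursor:
            anchor = new_node(reference[cursor:s], (cursor, s, True))
            connect(tails, anchor)
            tails = [anchor]
            graph.ref_path.append(anchor)
            segments.append(("anchor", anchor))
            cursor = s

        branch: dict[int, int | None] = {}
        new_tails: list[int] = []
        pass_through = False
        if e > s:  # reference branch node
            rnode = new_node(reference[s:e], (s, e, True))
            connect(tails, rnode)
            graph.ref_path.append(rnode)
            branch[0] = rnode
            new_tails.append(rnode)
        else:  # pure insertion: reference allele passes straight through
            branch[0] = None
            pass_through = True
        for j, core in enumerate(alt_cores, start=1):
            if core:
                anode = new_node(core.upper(), (s, e, False))
                connect(tails, anode)
                branch[j] = anode
                new_tails.append(anode)
            else:  # deletion allele: an edge will skip the reference bases
                branch[j] = None
                pass_through = True
        segments.append(("variant", vr, branch))
        tails = new_tails + (tails if pass_through else [])
        cursor = e

    if cursor < len(reference) or not graph.nodes:
        anchor = new_node(reference[cursor:], (cursor, len(reference), True))
        connect(tails, anchor)
        graph.ref_path.append(anchor)
        segments.append(("anchor", anchor))

    # thread one haplotype path per sample per phase
    for sample in samples:
        for phase in (0, 1):
            node_ids: list[int] = []
            for seg in segments:
                if seg[0] == "anchor":
                    node_ids.append(seg[1])
                else:
                    _, vr, branch = seg
                    gt = vr.genotypes.get(sample, (None, None, False))
                    allele = gt[phase]
                    if allele is None:
                        warnings.warn(
                            f"missing genotype for {sample} at "
                            f"{vr.chrom}:{vr.pos}; using reference allele",
                            stacklevel=2,
                        )
                        allele = 0
                    nid = branch[allele]
                    if nid is not None:
                        node_ids.append(nid)
            graph.haplotype_paths.append(
                HaplotypePath(sample_id=sample, phase=phase, node_ids=node_ids)
            )
    return graph


def path_sequence(graph: VariationGraph, path: list) -> str:
    """Concatenated sequence spelled by a walk over the graph's edges."""
    for a, b in zip(path, path[1:]):
        if (a, b) not in graph.edges:
            raise WalkError(f"no edge {a}->{b} in graph {graph.chrom}")
    return "".join(graph.nodes[nid] for nid in path)


# --------------------------------------------------------------------------
# GFA v1 serialization
# --------------------------------------------------------------------------


def write_gfa(graph: VariationGraph) -> str:
    """Serialise to GFA v1 with projection metadata as optional S-line tags.

    The reference path is the P-line named after the chromosome; haplotype
    P-lines are named ``<sample>#<phase>``.
    """
    out = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        seq = graph.nodes[nid]
        s, e, on_ref = graph.node_span[nid]
        out.append(f"S\t{nid}\t{seq}\tSR:i:{s}\tSE:i:{e}\tRF:i:{int(on_ref)}")
    for a, b in sorted(graph.edges):
        out.append(f"L\t{a}\t+\t{b}\t+\t0M")
    if graph.ref_path:
        segs = ",".join(f"{nid}+" for nid in graph.ref_path)
        out.append(f"P\t{graph.chrom}\t{segs}\t*")
    for hp in graph.haplotype_paths:
        segs = ",".join(f"{nid}+" for nid in hp.node_ids)
        out.append(f"P\t{hp.path_name}\t{segs}\t*")
    return "\n".join(out) + "\n"


def _parse_path_segments(field_: str, nodes: dict, name: str) -> list:
    ids = []
    if field_ in ("", "*"):
        return ids
    for seg in field_.split(","):
        if not seg or seg[-1] not in "+-":
            raise GFAFormatError(f"bad path step {seg!r} in P-line {name}")
        if seg[-1] == "-":
            raise GFAFormatError(
                f"reverse-orientation step {seg!r} unsupported (P-line {name})"
            )
        nid = int(seg[:-1])
        if nid not in nodes:
            raise GFAFormatError(f"P-line {name} references unknown segment {nid}")
        ids.append(nid)
    return ids


def read_gfa(text: str) -> VariationGraph:
    """Parse GFA v1 text produced by :func:`write_gfa` (or hand-written)."""
    nodes: dict[int, str] = {}
    spans: dict[int, tuple] = {}
    edges: set = set()
    paths: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 3:
                raise GFAFormatError(f"line {lineno}: S-line needs id and sequence")
            try:
                nid = int(fields[1])
            except ValueError as exc:
                raise GFAFormatError(
                    f"line {lineno}: non-integer segment id {fields[1]!r}"
                ) from exc
            nodes[nid] = fields[2].upper()
            opts = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2])
                for f in fields[3:]
                if f.count(":") >= 2
            )
            if {"SR", "SE", "RF"} <= set(opts):
                spans[nid] = (int(opts["SR"]), int(opts["SE"]), bool(int(opts["RF"])))
        elif tag == "L":
            if len(fields) < 5:
                raise GFAFormatError(f"line {lineno}: truncated L-line")
            edges.add((int(fields[1]), int(fields[3])))
        elif tag == "P":
            if len(fields) < 3:
                raise GFAFormatError(f"line {lineno}: truncated P-line")
            paths.append((fields[1], fields[2]))
        else:
            raise GFAFormatError(f"line {lineno}: unknown record type {tag!r}")
    for a, b in edges:
        if a not in nodes or b not in nodes:
            raise GFAFormatError(f"L-line references unknown segment ({a}, {b})")

    graph = VariationGraph(chrom="", nodes=nodes, edges=edges)
    for name, segfield in paths:
        ids = _parse_path_segments(segfield, nodes, name)
        if "#" in name:
            sample_id, phase = name.rsplit("#", 1)
            graph.haplotype_paths.append(
                HaplotypePath(sample_id=sample_id, phase=int(phase), node_ids=ids)
            )
        else:
            if graph.ref_path:
                raise GFAFormatError("multiple reference P-lines in one GFA")
            graph.chrom = name
            graph.ref_path = ids

    graph.node_span = spans
    _fill_missing_spans(graph)
    return graph


def _fill_missing_spans(graph: VariationGraph) -> None:
    """Best-effort reference projection when S-line tags are absent."""
    pos = 0
    for nid in graph.ref_path:
        if nid not in graph.node_span:
            graph.node_span[nid] = (pos, pos + len(graph.nodes[nid]), True)
        pos = graph.node_span[nid][1]
    missing = [n for n in graph.nodes if n not in graph.node_span]
    preds: dict[int, list] = {}
    for a, b in graph.edges:
        preds.setdefault(b, []).append(a)
    # relax: an untagged node inherits the projected end of a known predecessor
    for _ in range(len(missing) + 1):
        progressed = False
        for nid in list(missing):
            for p in preds.get(nid, []):
                if p in graph.node_span:
                    s, e, on_ref = graph.node_span[p]
                    start = e if on_ref else s
                    graph.node_span[nid] = (start, start, False)
                    missing.remove(nid)
                    progressed = True
                    break
        if not progressed:
            break
    for nid in missing:  # isolated nodes: pin to origin
        graph.node_span[nid] = (0, 0, False)


# --------------------------------------------------------------------------
# Region windows
# --------------------------------------------------------------------------


@dataclass
class RegionView:
    """Subgraph whose reference projection intersects a query window."""

    chrom: str
    start: int
    end: int  # possibly flank-extended
    nodes: dict
    edges: set
    node_span: dict


def region_window(
    graph: VariationGraph,
    chrom: str,
    start: int,
    end: int,
    flank: int = 0,
) -> RegionView:
    """Nodes and edges whose projection intersects ``[start, end + flank)``.

    ``flank`` lets motif windows anchored inside the region spell up to
    ``k - 1`` bases past its right edge. Regions beyond the chromosome end
    are clipped with a warning; inverted regions are an error.
    """
    if chrom != graph.chrom:
        raise ValueError(f"region on {chrom} queried against graph of {graph.chrom}")
    if start >= end:
        raise ValueError(f"inverted or empty region {chrom}:{start}-{end}")
    ref_len = graph.reference_length()
    if end > ref_len:
        warnings.warn(
            f"region {chrom}:{start}-{end} clipped to chromosome end {ref_len}",
            stacklevel=2,
        )
        end = ref_len
        if start >= end:
            raise ValueError(f"region {chrom}:{start}-{end} lies beyond the chromosome")
    hi = min(end + flank, ref_len)
    keep = {}
    for nid, (s, e, on_ref) in graph.node_span.items():
        # zero-length spans (insertion nodes) occupy the boundary point s
        if s < hi and max(e, s + 1) > start:
            keep[nid] = graph.nodes[nid]
    edges = {(a, b) for a, b in graph.edges if a in keep and b in keep}
    spans = {nid: graph.node_span[nid] for nid in keep}
    return RegionView(
        chrom=chrom, start=start, end=hi, nodes=keep, edges=edges, node_span=spans
    )


# --------------------------------------------------------------------------
# File ingest
# --------------------------------------------------------------------------


def read_fasta(path: str) -> dict:
    """All records of a FASTA file as {name: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_vcf(path: str, chroms: list[str] | None = None):
    """Read a (plain or bgzipped) VCF into per-chromosome VariantRecord lists.

    Returns ``(samples, {chrom: [VariantRecord, ...]})``. Symbolic alleles
    and breakends are rejected.
    """
    import pysam

    by_chrom: dict[str, list[VariantRecord]] = {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if chroms is not None and rec.chrom not in chroms:
                continue
            alts = tuple(rec.alts or ())
            if any(a is None or "<" in a or "[" in a or "]" in a for a in alts):
                raise ValueError(
                    f"symbolic or breakend allele at {rec.chrom}:{rec.pos} unsupported"
                )
            genotypes = {}
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT", (None, None))
                if gt is None or len(gt) != 2:
                    gt = (None, None)
                genotypes[sample] = (gt[0], gt[1], bool(call.phased))
            by_chrom.setdefault(rec.chrom, []).append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    genotypes=genotypes,
                )
            )
    return samples, by_chrom
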