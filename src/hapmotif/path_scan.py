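"""k-mer window enumeration along graph paths within query regions.

Haplotype mode slides a k-wide window along the reference path and every
haplotype path; recombinant mode additionally spells every directed walk
through the windowed subgraph, including allele combinations not observed
in any individual. Raw windows are aggregated per (sequence, projected
reference start) into :class:`KmerHit` records carrying haplotype
multiplicity and reference membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .genome_graph import RegionView, VariationGraph, region_window

REF_PATH_NAME = "ref"
RECOMBINANT_PATH_NAME = "recomb"

DEFAULT_MAX_WALKS = 10_000


class PathExplosionError(RuntimeError):
    """Recombinant walk enumeration exceeded the configured cap."""


@dataclass(frozen=True)
class Region:
    """A BED interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    @property
    def region_id(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


class RawKmer(NamedTuple):
    path_name: str  # "ref", "<sample>#<phase>", or "recomb"
    ref_start: int  # projected reference coordinate (0-based)
    sequence: str
    region_id: str


@dataclass
class KmerHit:
    """An aggregated k-length window observed on one or more paths."""

    sequence: str
    chrom: str
    ref_start: int  # 0-based half-open internally
    ref_stop: int
    strand: str
    haplotype_count: int
    in_reference: bool
    region_id: str


def read_bed(path: str) -> list[Region]:
    """Parse a BED file (3+ columns, 0-based half-open) into regions."""
    regions = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            name = fields[3] if len(fields) > 3 else ""
            regions.append(
                Region(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=name,
                )
            )
    return regions


def _path_projection(graph: VariationGraph, node_ids: list) -> tuple[str, list]:
    """Spelled sequence of a path and the reference coordinate of each base.

    Bases on reference-path nodes project to their genuine coordinates;
    bases inside alternate-branch nodes all project to the bubble's
    left-anchor end (the span start).
    """
    parts: list[str] = []
    proj: list[int] = []
    for nid in node_ids:
        seq = graph.nodes[nid]
        s, _e, on_ref = graph.node_span[nid]
        parts.append(seq)
        if on_ref:
            proj.extend(range(s, s + len(seq)))
        else:
            proj.extend([s] * len(seq))
    return "".join(parts), proj


def _windows_of(
    path_name: str, seq: str, proj: list, region: Region, k: int
) -> Iterable[RawKmer]:
    max_ns = k // 2
    for off in range(len(seq) - k + 1):
        start = proj[off]
        if not (region.start <= start < region.end):
            continue
        kmer = seq[off : off + k]
        if kmer.count("N") > max_ns:
            continue
        yield RawKmer(path_name, start, kmer, region.region_id)


def _recombinant_walks(
    view: RegionView, region: Region, k: int, max_walks: int
) -> Iterable[RawKmer]:
    """Spell every k-base directed walk whose start projects into the region."""
    succ: dict[int, list] = {}
    for a, b in view.edges:
        succ.setdefault(a, []).append(b)
    for nid in succ:
        succ[nid].sort()
    produced = 0
    max_ns = k // 2

    for nid in sorted(view.nodes):
        seq = view.nodes[nid]
        s, _e, on_ref = view.node_span[nid]
        for off in range(len(seq)):
            start = (s + off) if on_ref else s
            if not (region.start <= start < region.end):
                continue
            # DFS over (current node, text gathered so far)
            stack = [(nid, seq[off:])]
            while stack:
                cur, text = stack.pop()
                if len(text) >= k:
                    produced += 1
                    if produced > max_walks:
                        raise PathExplosionError(
                            f"more than {max_walks} recombinant walks in window "
                            f"{region.chrom}:{region.start}-{region.end}"
                        )
                    kmer = text[:k]
                    if kmer.count("N") <= max_ns:
                        yield RawKmer(RECOMBINANT_PATH_NAME, start, kmer, region.region_id)
                    continue
                for nxt in succ.get(cur, ()):
                    stack.append((nxt, text + view.nodes[nxt]))


def enumerate_kmer_paths(
    graph: VariationGraph,
    region: Region,
    k: int,
    mode: str = "haplotype",
    max_walks: int = DEFAULT_MAX_WALKS,
) -> list[RawKmer]:
    """All k-length windows over the region's paths, tagged by source path.

    ``mode="haplotype"`` scans the reference path plus each sample haplotype
    path; ``mode="recombinant"`` additionally spells every directed walk in
    the windowed subgraph (capped at ``max_walks``). A window is kept when
    its projected start lies inside the region; it may extend up to k-1
    bases past the region's right edge.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("haplotype", "recombinant"):
        raise ValueError(f"unknown scan mode {mode!r}")
    raws: list[RawKmer] = []
    named_paths = [(REF_PATH_NAME, graph.ref_path)] + [
        (hp.path_name, hp.node_ids) for hp in graph.haplotype_paths
    ]
    for path_name, node_ids in named_paths:
        seq, proj = _path_projection(graph, node_ids)
        raws.extend(_windows_of(path_name, seq, proj, region, k))
    if mode == "recombinant":
        view = region_window(graph, region.chrom, region.start, region.end, flank=k - 1)
        raws.extend(_recombinant_walks(view, region, k, max_walks))
    return raws


def aggregate_hits(raws: list[RawKmer], graph: VariationGraph) -> list[KmerHit]:
    """Group raw windows by (sequence, projected start) into plus-strand hits.

    ``haplotype_count`` is the number of distinct sample haplotype paths in
    the group; the reference path contributes only the ``in_reference`` flag
    and recombinant walks contribute neither.
    """
    k = len(raws[0].sequence) if raws else 0
    groups: dict[tuple, set] = {}
    for raw in raws:
        if len(raw.sequence) != k:
            raise ValueError("mixed k-mer lengths passed to aggregate_hits")
        key = (raw.sequence, raw.ref_start, raw.region_id)
        groups.setdefault(key, set()).add(raw.path_name)
    hits = []
    for (sequence, ref_start, region_id) in sorted(groups):
        names = groups[(sequence, ref_start, region_id)]
        hap_names = names - {REF_PATH_NAME, RECOMBINANT_PATH_NAME}
        hits.append(
            KmerHit(
                sequence=sequence,
                chrom=graph.chrom,
                ref_start=ref_start,
                ref_stop=ref_start + k,
                strand="+",
                haplotype_count=len(hap_names),
                in_reference=REF_PATH_NAME in names,
                region_id=region_id,
            )
        )
    return hits
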