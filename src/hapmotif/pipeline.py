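"""End-to-end scan orchestration: enumerate, score, test, pool, filter.

For each motif a single scaled scoring matrix and exact P-value table are
built up front; hits from every region (both strands) are scored against
them, and q-values are computed per motif over the pooled P-values of all
scored k-mer windows in all scanned regions. Occurrences are reported with
1-based inclusive coordinates, sorted by ascending P-value.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from . import path_scan, scoring
from .genome_graph import VariationGraph
from .motif_io import PWM, Background, pwm_to_probabilities
from .path_scan import Region

DEFAULT_PVALUE_THRESHOLD = 1e-4


@dataclass
class ScanParams:
    """Knobs of one scan run."""

    background: Background = field(default_factory=Background.uniform)
    pseudocount: float = 0.1
    p_threshold: float | None = None  # strict '<' filter; None keeps everything
    q_threshold: float | None = None
    compute_qvalues: bool = True
    mode: str = "haplotype"  # or "recombinant"
    max_walks: int = path_scan.DEFAULT_MAX_WALKS
    both_strands: bool = True


@dataclass
class MotifOccurrence:
    """One scored, tested candidate binding site — a row of the report."""

    motif_id: str
    motif_name: str
    region_id: str
    chrom: str
    start: int  # 1-based inclusive (reporting convention)
    stop: int
    strand: str
    score: float  # unscaled log-odds
    pvalue: float
    qvalue: float
    sequence: str
    haplotype_count: int
    haplotype_fraction: float
    flag: str  # "ref" | "non.ref"


@dataclass
class _MotifBundle:
    """Per-motif precomputed scoring machinery."""

    pwm: PWM
    spssm: scoring.ScaledPSSM
    spssm_rc: scoring.ScaledPSSM
    table: scoring.PValueTable
    table_rc: scoring.PValueTable


def _prepare_motif(pwm: PWM, params: ScanParams) -> _MotifBundle:
    probs = pwm_to_probabilities(pwm, params.background, params.pseudocount)
    pssm = scoring.build_pssm(probs, params.background)
    spssm = scoring.scale_pssm(pssm)
    spssm_rc = scoring.reverse_complement_pssm(spssm)
    table = scoring.build_pvalue_table(spssm, params.background)
    table_rc = scoring.build_pvalue_table(spssm_rc, params.background)
    return _MotifBundle(
        pwm=pwm, spssm=spssm, spssm_rc=spssm_rc, table=table, table_rc=table_rc
    )


def _scan_graph_one_motif(
    graph: VariationGraph,
    bundle: _MotifBundle,
    regions: list[Region],
    params: ScanParams,
) -> list[MotifOccurrence]:
    """All scored occurrences of one motif on one graph (q-values unset)."""
    k = bundle.spssm.width
    total_haps = max(graph.n_haplotypes, 1)
    occurrences: list[MotifOccurrence] = []
    for region in regions:
        raws = path_scan.enumerate_kmer_paths(
            graph, region, k, mode=params.mode, max_walks=params.max_walks
        )
        hits = path_scan.aggregate_hits(raws, graph)
        strands = ("+", "-") if params.both_strands else ("+",)
        for hit in hits:
            for strand in strands:
                if strand == "+":
                    s = scoring.score_kmer(bundle.spssm, hit.sequence)
                    pval = bundle.table.pvalue(s)
                    seq_out = hit.sequence
                    logodds = scoring.unscale_score(bundle.spssm, s)
                else:
                    # the reverse-complement matrix scores the minus strand
                    # at the same reference coordinates
                    s = scoring.score_kmer(bundle.spssm_rc, hit.sequence)
                    pval = bundle.table_rc.pvalue(s)
                    seq_out = scoring.reverse_complement(hit.sequence)
                    logodds = scoring.unscale_score(bundle.spssm_rc, s)
                occurrences.append(
                    MotifOccurrence(
                        motif_id=bundle.pwm.motif_id,
                        motif_name=bundle.pwm.name,
                        region_id=hit.region_id,
                        chrom=hit.chrom,
                        start=hit.ref_start + 1,
                        stop=hit.ref_start + k,
                        strand=strand,
                        score=round(logodds, 3),
                        pvalue=pval,
                        qvalue=float("nan"),
                        sequence=seq_out,
                        haplotype_count=hit.haplotype_count,
                        haplotype_fraction=hit.haplotype_count / total_haps,
                        flag="ref" if hit.in_reference else "non.ref",
                    )
                )
    return occurrences


def _chrom_sort_key(occ: MotifOccurrence):
    return (
        occ.pvalue,
        occ.chrom,
        occ.start,
        occ.strand,
        occ.motif_id,
        occ.sequence,
        occ.region_id,
    )


def _scan_chromosome(args) -> list[MotifOccurrence]:
    graph, bundles, regions, params = args
    out: list[MotifOccurrence] = []
    for bundle in bundles:
        out.extend(_scan_graph_one_motif(graph, bundle, regions, params))
    return out


def scan_graphs(
    graphs: list[VariationGraph],
    motifs: list[PWM],
    regions: list[Region],
    params: ScanParams | None = None,
    cores: int = 1,
) -> list[MotifOccurrence]:
    """Scan one or more chromosome graphs for one or more motifs.

    Chromosomes may be scanned in parallel; q-values are computed per motif
    over the pooled P-values of every scored window across all regions and
    chromosomes, so results are independent of scan order and core count.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    params = params or ScanParams()
    by_chrom: dict[str, list[Region]] = {}
    graph_chroms = {g.chrom for g in graphs}
    for region in regions:
        if region.chrom not in graph_chroms:
            warnings.warn(
                f"region {region.region_id} has no matching chromosome graph; skipped",
                stacklevel=2,
            )
            continue
        by_chrom.setdefault(region.chrom, []).append(region)

    bundles = [_prepare_motif(m, params) for m in motifs]
    jobs = [
        (graph, bundles, by_chrom[graph.chrom], params)
        for graph in sorted(graphs, key=lambda g: g.chrom)
        if graph.chrom in by_chrom
    ]
    if cores > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=cores) as pool:
            chunks = list(pool.map(_scan_chromosome, jobs))
    else:
        chunks = [_scan_chromosome(job) for job in jobs]
    occurrences = [occ for chunk in chunks for occ in chunk]

    if params.compute_qvalues and occurrences:
        for motif in motifs:
            idx = [
                i for i, occ in enumerate(occurrences) if occ.motif_id == motif.motif_id
            ]
            if not idx:
                continue
            qvals = scoring.benjamini_hochberg(
                [occurrences[i].pvalue for i in idx]
            )
            for i, q in zip(idx, qvals):
                occurrences[i] = replace(occurrences[i], qvalue=float(q))

    occurrences.sort(key=_chrom_sort_key)
    return apply_significance(occurrences, params.p_threshold, params.q_threshold)


def scan(
    graph: VariationGraph,
    motifs: list[PWM],
    regions: list[Region],
    params: ScanParams | None = None,
) -> list[MotifOccurrence]:
    """Single-graph scan; errors if a region names a different chromosome."""
    for region in regions:
        if region.chrom != graph.chrom:
            raise ValueError(
                f"region {region.region_id} does not match graph chromosome "
                f"{graph.chrom}"
            )
    return scan_graphs([graph], motifs, regions, params)


def apply_significance(
    occurrences: list[MotifOccurrence],
    p_threshold: float | None,
    q_threshold: float | None = None,
) -> list[MotifOccurrence]:
    """Strict P-value filter plus optional q-value filter; order preserved.

    A threshold >= 1 disables the corresponding filter (P-values can equal
    exactly 1, and a threshold of 1 means "keep everything").
    """
    out = occurrences
    if p_threshold is not None and p_threshold < 1.0:
        out = [o for o in out if o.pvalue < p_threshold]
    if q_threshold is not None and q_threshold < 1.0:
        out = [o for o in out if not np.isnan(o.qvalue) and o.qvalue < q_threshold]
    return out


def classify_sites(
    occurrences: list[MotifOccurrence],
    p_threshold: float = DEFAULT_PVALUE_THRESHOLD,
) -> dict:
    """Categorise candidate sites of one motif by how variants affect them.

    Sites (grouped by chrom, start, strand) fall into: ``non-ref-only`` (no
    reference spelling passes), ``ref-only`` (only the reference spelling
    passes), ``shared-modulated`` (both pass with different scores) or
    ``shared-equal``. Returns per-site categories plus counts/percentages.
    """
    motif_ids = {o.motif_id for o in occurrences}
    if len(motif_ids) > 1:
        raise ValueError("classify_sites expects occurrences of a single motif")
    sites: dict[tuple, list[MotifOccurrence]] = {}
    for occ in occurrences:
        sites.setdefault((occ.chrom, occ.start, occ.strand), []).append(occ)
    categories: dict[tuple, str] = {}
    for key, members in sites.items():
        passing = [o for o in members if o.pvalue < p_threshold]
        if not passing:
            continue
        # a member may be carried by the reference, by haplotypes, or both
        # (an invariant site is one member with flag "ref" and full support)
        ref_pass = any(o.flag == "ref" for o in passing)
        hap_pass = any(o.haplotype_count > 0 for o in passing)
        if not ref_pass:
            categories[key] = "non-ref-only"
        elif not hap_pass:
            categories[key] = "ref-only"
        else:
            scores = {o.score for o in passing}
            categories[key] = "shared-modulated" if len(scores) > 1 else "shared-equal"
    counts = {
        c: sum(1 for v in categories.values() if v == c)
        for c in ("ref-only", "non-ref-only", "shared-modulated", "shared-equal")
    }
    total = sum(counts.values())
    percentages = {
        c: (100.0 * n / total if total else 0.0) for c, n in counts.items()
    }
    return {"categories": categories, "counts": counts, "percentages": percentages}
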