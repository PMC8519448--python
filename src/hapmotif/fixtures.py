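"""Deterministic toy dataset generation with an independent expected-hit oracle.

``make_toy_dataset`` writes a uniform-random reference FASTA, a phased VCF
(SNPs and small indels), a BED region file and JASPAR motif text, optionally
planting motif consensus instances either in the reference or on the
alternate branch of a dedicated SNP. Alongside the files it produces a
manifest of every expected significant occurrence.

The manifest is computed WITHOUT the scanning machinery: haplotype sequences
are materialised by direct string edits, scored by direct log-odds
summation, and P-values obtained by exhaustive enumeration over all 4^k
k-mers (fixture motifs are limited to k <= 8). This keeps the oracle
independent of the graph, scoring and pipeline modules it is used to test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .motif_io import NT_INDEX, NUCLEOTIDES, PWM, write_jaspar

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ORACLE_MAX_WIDTH = 8


class PlantingError(ValueError):
    """Planted sites or variants overlap infeasibly."""


@dataclass(frozen=True)
class PlantedSite:
    """A motif consensus written into the toy chromosome.

    ``branch="ref"`` writes the consensus into the reference itself;
    ``branch="alt"`` writes it into the reference and then damages the most
    informative position with a SNP whose REF is the worst-scoring base and
    whose ALT restores the consensus — so the intact site exists only on the
    haplotypes carrying the alternate allele.
    """

    pwm: PWM
    position: int  # 0-based reference start of the planted instance
    branch: str = "ref"  # "ref" | "alt"
    carrier_sample: int = 0  # index of the 0|1 carrier for branch="alt"


@dataclass(frozen=True)
class _Variant:
    pos: int  # 1-based, VCF style
    ref: str
    alts: tuple
    genotypes: tuple  # ((a, b), ...) aligned with the sample list, phased

    def core(self) -> tuple[int, int, list[str]]:
        alleles = (self.ref,) + self.alts
        t = 0
        while (
            t < len(self.ref)
            and all(t < len(a) and a[t] == self.ref[t] for a in alleles)
            and not all(len(a) == t + 1 for a in alleles)
        ):
            t += 1
        return self.pos - 1 + t, self.pos - 1 + len(self.ref), [a[t:] for a in self.alts]


@dataclass(frozen=True)
class ManifestHit:
    """One expected significant occurrence (1-based inclusive coordinates)."""

    chrom: str
    start: int
    stop: int
    strand: str
    sequence: str
    pvalue: float
    flag: str  # "ref" | "non.ref"
    haplotype_count: int


@dataclass
class ToyDataset:
    chrom: str
    reference: str
    samples: list
    variants: list
    fasta_path: str
    vcf_path: str
    bed_path: str
    motif_paths: list
    manifest_path: str
    manifest: list = field(default_factory=list)


def make_consensus_pwm(
    consensus: str, motif_id: str = "TOY1", name: str = "TOY", strength: int = 97
) -> PWM:
    """A count PWM strongly peaked on the given consensus sequence."""
    k = len(consensus)
    matrix = np.ones((4, k), dtype=float)
    for i, ch in enumerate(consensus.upper()):
        matrix[NT_INDEX[ch], i] = strength
    return PWM(motif_id=motif_id, name=name, matrix=matrix, is_probability=False)


# --------------------------------------------------------------------------
# Independent oracle: direct log-odds + exhaustive P-values
# --------------------------------------------------------------------------


def _oracle_logodds(pwm: PWM, pseudocount: float = 0.1) -> np.ndarray:
    """log2 odds vs uniform background, computed directly from counts."""
    colsums = pwm.matrix.sum(axis=0)
    probs = (pwm.matrix + pseudocount * 0.25) / (colsums + pseudocount)
    return np.log2(probs / 0.25)


def _oracle_score(logodds: np.ndarray, seq: str) -> float:
    return float(sum(logodds[NT_INDEX[c], i] for i, c in enumerate(seq)))


def _oracle_pvalue_fn(logodds: np.ndarray):
    """Exhaustive survival function over all 4^k sequences (uniform bg)."""
    k = logodds.shape[1]
    if k > _ORACLE_MAX_WIDTH:
        raise ValueError(f"oracle limited to width <= {_ORACLE_MAX_WIDTH}, got {k}")
    scores = np.zeros(1)
    for i in range(k):
        scores = (scores[:, None] + logodds[:, i][None, :]).ravel()
    scores.sort()
    n = float(len(scores))

    def pvalue(s: float) -> float:
        idx = np.searchsorted(scores, s - 1e-9, side="left")
        return (len(scores) - idx) / n

    return pvalue


def _haplotype_string(
    reference: str, variants: list, alleles: list
) -> tuple[str, list]:
    """Apply one allele choice per variant by string edits.

    Returns the haplotype sequence and, per base, its projected reference
    coordinate (bases introduced by an alternate allele project to the
    replaced interval's left end).
    """
    parts: list[str] = []
    proj: list[int] = []
    cursor = 0
    for v, allele in zip(variants, alleles):
        if allele == 0:
            continue
        s, e, cores = v.core()
        if s < cursor:
            continue  # overlapping record: first wins, as in graph construction
        parts.append(reference[cursor:s])
        proj.extend(range(cursor, s))
        core = cores[allele - 1]
        parts.append(core)
        proj.extend([s] * len(core))
        cursor = e
    parts.append(reference[cursor:])
    proj.extend(range(cursor, len(reference)))
    return "".join(parts), proj


def _oracle_manifest(
    chrom: str,
    reference: str,
    variants: list,
    samples: list,
    pwms: list,
    region: tuple,
    p_threshold: float,
    pseudocount: float,
) -> list[ManifestHit]:
    """Expected significant occurrences by brute-force string enumeration."""
    rstart, rend = region
    hap_strings = []
    for si in range(len(samples)):
        for phase in (0, 1):
            alleles = [v.genotypes[si][phase] for v in variants]
            hap_strings.append(_haplotype_string(reference, variants, alleles))
    ref_proj = list(range(len(reference)))

    hits: list[ManifestHit] = []
    for pwm in pwms:
        k = pwm.width
        logodds = _oracle_logodds(pwm, pseudocount)
        pvalue = _oracle_pvalue_fn(logodds)

        # gather every (sequence, projected start) with its supporting paths
        occurrences: dict[tuple, set] = {}

        def collect(seq: str, proj: list, tag):
            for off in range(len(seq) - k + 1):
                start = proj[off]
                if rstart <= start < rend:
                    occurrences.setdefault((seq[off : off + k], start), set()).add(tag)

        collect(reference, ref_proj, "ref")
        for hi, (hseq, hproj) in enumerate(hap_strings):
            collect(hseq, hproj, hi)

        for (seq, start), tags in sorted(occurrences.items()):
            hap_count = len(tags - {"ref"})
            flag = "ref" if "ref" in tags else "non.ref"
            for strand, oriented in (
                ("+", seq),
                ("-", seq.translate(_COMPLEMENT)[::-1]),
            ):
                p = pvalue(_oracle_score(logodds, oriented))
                if p < p_threshold:
                    hits.append(
                        ManifestHit(
                            chrom=chrom,
                            start=start + 1,
                            stop=start + k,
                            strand=strand,
                            sequence=oriented,
                            pvalue=p,
                            flag=flag,
                            haplotype_count=hap_count,
                        )
                    )
    hits.sort(key=lambda h: (h.pvalue, h.start, h.strand, h.sequence))
    return hits


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------


def _random_reference(rng: np.random.Generator, length: int) -> list:
    return list(rng.choice(list(NUCLEOTIDES), size=length))


def _phased_genotypes(
    rng: np.random.Generator, n_samples: int, af: float
) -> tuple:
    return tuple(
        (int(rng.random() < af), int(rng.random() < af)) for _ in range(n_samples)
    )


def make_toy_dataset(
    seed: int,
    out_dir: str,
    chrom: str = "chr1",
    chrom_len: int = 1200,
    n_samples: int = 4,
    n_snps: int = 6,
    n_indels: int = 2,
    planted: list | None = None,
    motifs: list | None = None,
    allele_freq: float = 0.3,
    p_threshold: float = 1e-4,
    pseudocount: float = 0.1,
    region: tuple | None = None,
) -> ToyDataset:
    """Write a deterministic toy FASTA/VCF/BED/motif bundle plus manifest.

    Random variants never overlap each other or the planted sites. Re-running
    with the same seed reproduces every file byte for byte.
    """
    if chrom_len < 200:
        raise ValueError("chrom_len must be >= 200")
    planted = planted or []
    rng = np.random.default_rng(seed)
    ref_chars = _random_reference(rng, chrom_len)

    blocked = np.zeros(chrom_len, dtype=bool)  # positions unavailable to variants
    variants: list[_Variant] = []
    pwms: list[PWM] = list(motifs or [])  # scanned but not planted

    # plant motif instances first so their footprint is reserved
    for site in planted:
        pwm = site.pwm
        k = pwm.width
        if site.position < 0 or site.position + k > chrom_len:
            raise PlantingError(f"planted site at {site.position} outside chromosome")
        if blocked[site.position : site.position + k].any():
            raise PlantingError(f"planted site at {site.position} overlaps another")
        consensus = pwm.consensus()
        ref_chars[site.position : site.position + k] = list(consensus)
        blocked[max(site.position - 1, 0) : site.position + k + 1] = True
        if pwm.motif_id not in {p.motif_id for p in pwms}:
            pwms.append(pwm)
        if site.branch == "alt":
            logodds = _oracle_logodds(pwm, pseudocount)
            col = int(np.argmax(logodds.max(axis=0) - logodds.min(axis=0)))
            good = consensus[col]
            bad = NUCLEOTIDES[int(np.argmin(logodds[:, col]))]
            gpos = site.position + col
            ref_chars[gpos] = bad  # the reference carries the broken spelling
            gts = tuple(
                (0, 1) if si == site.carrier_sample else (0, 0)
                for si in range(n_samples)
            )
            variants.append(_Variant(pos=gpos + 1, ref=bad, alts=(good,), genotypes=gts))
        elif site.branch != "ref":
            raise PlantingError(f"unknown branch {site.branch!r}")

    reference = "".join(ref_chars)

    # random variants in the unreserved space, kept well apart
    free = np.flatnonzero(~blocked[5 : chrom_len - 10]) + 5
    rng.shuffle(free)
    taken: list[tuple] = [(v.pos - 1, v.pos - 1 + len(v.ref)) for v in variants]

    def reserve(s: int, e: int) -> bool:
        for a, b in taken:
            if s < b + 5 and a < e + 5:
                return False
        taken.append((s, e))
        return True

    placed_snps = placed_indels = 0
    for p in free:
        if placed_snps >= n_snps and placed_indels >= n_indels:
            break
        if placed_snps < n_snps:
            if not reserve(p, p + 1):
                continue
            ref_b = reference[p]
            alt_b = str(rng.choice([b for b in NUCLEOTIDES if b != ref_b]))
            variants.append(
                _Variant(
                    pos=p + 1,
                    ref=ref_b,
                    alts=(alt_b,),
                    genotypes=_phased_genotypes(rng, n_samples, allele_freq),
                )
            )
            placed_snps += 1
        else:
            dlen = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                if p + 1 + dlen > chrom_len or not reserve(p, p + 1 + dlen):
                    continue
                ref_a = reference[p : p + 1 + dlen]
                alt_a = reference[p]
            else:  # insertion
                if not reserve(p, p + 1):
                    continue
                ref_a = reference[p]
                alt_a = ref_a + "".join(rng.choice(list(NUCLEOTIDES), size=dlen))
            variants.append(
                _Variant(
                    pos=p + 1,
                    ref=ref_a,
                    alts=(alt_a,),
                    genotypes=_phased_genotypes(rng, n_samples, allele_freq),
                )
            )
            placed_indels += 1
    variants.sort(key=lambda v: v.pos)

    samples = [f"SAMPLE{i + 1}" for i in range(n_samples)]
    region = region or (0, chrom_len)

    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "toy.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, chrom_len, 60):
            fh.write(reference[i : i + 60] + "\n")

    vcf_path = os.path.join(out_dir, "toy.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            gt_str = "\t".join(f"{a}|{b}" for a, b in v.genotypes)
            fh.write(
                f"{chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t{gt_str}\n"
            )

    bed_path = os.path.join(out_dir, "toy.bed")
    with open(bed_path, "w") as fh:
        fh.write(f"{chrom}\t{region[0]}\t{region[1]}\ttoyregion\n")

    motif_paths = []
    for pwm in pwms:
        mpath = os.path.join(out_dir, f"{pwm.motif_id}.jaspar")
        with open(mpath, "w") as fh:
            fh.write(write_jaspar(pwm))
        motif_paths.append(mpath)

    manifest = _oracle_manifest(
        chrom, reference, variants, samples, pwms, region, p_threshold, pseudocount
    )
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("chrom\tstart\tstop\tstrand\tsequence\tpvalue\tflag\thaplotype_count\n")
        for h in manifest:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.stop}\t{h.strand}\t{h.sequence}\t"
                f"{h.pvalue:.6e}\t{h.flag}\t{h.haplotype_count}\n"
            )

    return ToyDataset(
        chrom=chrom,
        reference=reference,
        samples=samples,
        variants=variants,
        fasta_path=fasta_path,
        vcf_path=vcf_path,
        bed_path=bed_path,
        motif_paths=motif_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )
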