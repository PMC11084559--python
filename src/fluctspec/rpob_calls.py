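"""rpoB mutation identification from Sanger-derived reads.

Reads are oriented (forward vs reverse complement), aligned semi-globally
to the rpoB CDS reference (read end-gaps free), and variants extracted
from the alignment.  Calls are annotated with codon number, amino-acid
change and the rifampicin-resistance determining region (RRDR) cluster:
cluster I (aa 507-533 / nt 1520-1598), cluster II (aa 563-572 /
nt 1687-1715) and cluster III (aa 687 / nt 2060-2062).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .spectrum_models import classify_substitution

__all__ = [
    "Reference",
    "MutationCall",
    "AlignmentResult",
    "RRDR_CLUSTERS",
    "UnalignableReadError",
    "orient_and_align",
    "extract_variants",
    "annotate_call",
    "call_read",
    "calls_to_tables",
    "write_vcf",
    "load_reference",
]

# RRDR cluster boundaries, 1-based inclusive CDS nucleotide positions
RRDR_CLUSTERS = {"I": (1520, 1598), "II": (1687, 1715), "III": (2060, 2062)}

DEFAULT_SCORING = {"match": 2.0, "mismatch": -3.0, "gap_open": -5.0, "gap_extend": -2.0}
DEFAULT_IDENTITY_FLOOR = 0.80


class UnalignableReadError(ValueError):
    """Best alignment identity fell below the configured floor."""


@dataclass(frozen=True)
class Reference:
    """rpoB CDS reference with its genomic anchor."""

    gene_id: str
    cds_sequence: str
    genome_accession: str = ""
    genome_offset: int = 1

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        if len(seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if set(seq) - set("ACGT"):
            raise ValueError("CDS alphabet must be A/C/G/T")
        object.__setattr__(self, "cds_sequence", seq)

    def codon(self, codon_number: int) -> str:
        start = 3 * (codon_number - 1)
        return self.cds_sequence[start : start + 3]


@dataclass(frozen=True)
class MutationCall:
    isolate_id: str
    cds_pos: int
    kind: str  # substitution | insertion | deletion
    ref_allele: str
    alt_allele: str
    codon_number: int = 0
    aa_change: str = ""
    cluster: str = ""
    frame_preserving: bool | None = None


@dataclass(frozen=True)
class AlignmentResult:
    oriented_read: str
    ref_window: tuple[int, int]
    pairs: tuple  # of (ref_pos | None, read_pos | None), 1-based
    score: float
    strand_used: str
    identity: float


def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    # semi-global: unaligned flanks on either sequence are free
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.wildcard = "N"
    return aligner


def _pairs_from_alignment(alignment) -> list[tuple[int | None, int | None]]:
    """Flatten a Biopython alignment into 1-based (ref_pos, read_pos) pairs."""
    pairs: list[tuple[int | None, int | None]] = []
    blocks_t, blocks_q = alignment.aligned
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            for t in range(prev_t, t0):  # deletion in read
                pairs.append((t + 1, None))
            for q in range(prev_q, q0):  # insertion in read
                pairs.append((None, q + 1))
        for t, q in zip(range(t0, t1), range(q0, q1)):
            pairs.append((t + 1, q + 1))
        prev_t, prev_q = t1, q1
    return pairs


def orient_and_align(read: str, ref: Reference,
                     scoring: dict | None = None,
                     identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> AlignmentResult:
    """Align a read to the CDS, trying both strands.

    Returns the higher-scoring of the forward and reverse-complement
    alignments; raises UnalignableReadError when the best identity over
    aligned read columns is below ``identity_floor``.
    """
    read = read.upper()
    if len(read) < 50:
        raise ValueError("read shorter than 50 nt")
    if set(read) - set("ACGTN"):
        raise ValueError("read alphabet must be A/C/G/T/N")
    aligner = _make_aligner(scoring or DEFAULT_SCORING)
    candidates = [
        ("forward", read),
        ("reverse-complement", str(Seq(read).reverse_complement())),
    ]
    best = None
    for strand, oriented in candidates:
        alns = aligner.align(ref.cds_sequence, oriented)
        aln = alns[0]
        if best is None or aln.score > best[2].score:
            best = (strand, oriented, aln)
    strand, oriented, aln = best
    pairs = _pairs_from_alignment(aln)
    aligned_cols = [(t, q) for t, q in pairs if t is not None and q is not None]
    if not aligned_cols:
        raise UnalignableReadError("no aligned columns")
    matches = sum(
        1 for t, q in aligned_cols if ref.cds_sequence[t - 1] == oriented[q - 1]
    )
    identity = matches / len(aligned_cols)
    if identity < identity_floor:
        raise UnalignableReadError(
            f"best alignment identity {identity:.3f} below floor {identity_floor}"
        )
    ref_positions = [t for t, _ in aligned_cols]
    return AlignmentResult(
        oriented_read=oriented,
        ref_window=(min(ref_positions), max(ref_positions)),
        pairs=tuple(pairs),
        score=float(aln.score),
        strand_used=strand,
        identity=identity,
    )


def _left_normalize(cds: str, pos: int, ref_allele: str, alt_allele: str):
    """Shift an indel to the smallest CDS position giving the same edit."""
    if len(ref_allele) > 0 and len(alt_allele) == 0:  # deletion
        seq = ref_allele
        while pos > 1 and cds[pos - 2] == seq[-1]:
            pos -= 1
            seq = cds[pos - 1] + seq[:-1]
        return pos, seq, ""
    if len(alt_allele) > 0 and len(ref_allele) == 0:  # insertion after pos
        seq = alt_allele
        while pos >= 1 and seq and cds[pos - 1] == seq[-1]:
            seq = cds[pos - 1] + seq[:-1]
            pos -= 1
        return pos, "", seq
    return pos, ref_allele, alt_allele


def extract_variants(aln: AlignmentResult, ref: Reference,
                     isolate_id: str = "") -> list[MutationCall]:
    """Turn alignment columns into mutation calls.

    Each mismatched column yields one substitution; each gap run yields
    one indel (left-normalised).  Read N positions are uninformative and
    produce no call.
    """
    cds = ref.cds_sequence
    read = aln.oriented_read
    calls: list[MutationCall] = []
    i = 0
    pairs = aln.pairs
    n = len(pairs)
    last_ref = None
    while i < n:
        t, q = pairs[i]
        if t is not None and q is not None:
            rb, qb = cds[t - 1], read[q - 1]
            if qb != "N" and rb != qb:
                calls.append(MutationCall(isolate_id, t, "substitution", rb, qb))
            last_ref = t
            i += 1
        elif q is None:  # deletion run
            j = i
            while j < n and pairs[j][1] is None:
                j += 1
            del_positions = [pairs[k][0] for k in range(i, j)]
            pos0 = del_positions[0]
            seq = "".join(cds[p - 1] for p in del_positions)
            pos, ref_a, alt_a = _left_normalize(cds, pos0, seq, "")
            calls.append(MutationCall(isolate_id, pos, "deletion", ref_a, alt_a,
                                      frame_preserving=len(ref_a) % 3 == 0))
            i = j
        else:  # insertion run
            j = i
            while j < n and pairs[j][0] is None:
                j += 1
            ins = "".join(read[pairs[k][1] - 1] for k in range(i, j))
            if "N" in ins:
                i = j
                continue
            anchor = last_ref if last_ref is not None else 0
            pos, ref_a, alt_a = _left_normalize(cds, anchor, "", ins)
            calls.append(MutationCall(isolate_id, max(pos, 1), "insertion",
                                      ref_a, alt_a,
                                      frame_preserving=len(alt_a) % 3 == 0))
            i = j
    return [annotate_call(c, ref) for c in calls]


def _assign_cluster(cds_pos: int) -> str:
    for name, (lo, hi) in RRDR_CLUSTERS.items():
        if lo <= cds_pos <= hi:
            return name
    return "outside"


def annotate_call(call: MutationCall, ref: Reference) -> MutationCall:
    """Fill cluster, codon number and amino-acid change."""
    if call.cds_pos > len(ref.cds_sequence):
        raise ValueError("cds_pos beyond reference length")
    codon_number = math.ceil(call.cds_pos / 3)
    cluster = _assign_cluster(call.cds_pos)
    aa_change = ""
    if call.kind == "substitution":
        codon = ref.codon(codon_number)
        offset = (call.cds_pos - 1) % 3
        alt_codon = codon[:offset] + call.alt_allele + codon[offset + 1 :]
        # bacterial (table 11) translation; identical to standard for
        # internal codons
        aa_ref = str(Seq(codon).translate(table=11))
        aa_alt = str(Seq(alt_codon).translate(table=11))
        aa_change = f"{aa_ref}{codon_number}{aa_alt}"
    return replace(call, codon_number=codon_number, cluster=cluster,
                   aa_change=aa_change)


def call_read(isolate_id: str, read: str, ref: Reference,
              scoring: dict | None = None) -> list[MutationCall]:
    """Orient, align and call one read."""
    aln = orient_and_align(read, ref, scoring)
    return extract_variants(aln, ref, isolate_id)


def _category_for(call: MutationCall) -> str:
    if call.kind == "substitution":
        return classify_substitution(call.ref_allele, call.alt_allele)
    return call.kind


def calls_to_tables(calls_by_isolate: dict[str, list[MutationCall]],
                    metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-isolate call table joined with strain/glucose metadata.

    Isolates with no call inside RRDR clusters I/II get one
    ``none_detected`` row.  Isolates with several RRDR calls keep them
    all and are flagged for review.
    """
    meta = metadata.set_index("isolate_id")
    missing = [iso for iso in calls_by_isolate if iso not in meta.index]
    if missing:
        raise KeyError(f"isolates missing metadata: {sorted(missing)}")
    rows = []
    for iso, calls in calls_by_isolate.items():
        strain = meta.at[iso, "strain"]
        glucose = meta.at[iso, "glucose"]
        rrdr = [c for c in calls if c.cluster in ("I", "II")]
        flag = len(rrdr) > 1
        if not rrdr:
            rows.append(dict(isolate_id=iso, strain=strain, glucose=glucose,
                             cds_pos=pd.NA, kind="none", ref_allele="",
                             alt_allele="", codon_number=pd.NA, aa_change="",
                             cluster="", category="none_detected",
                             multi_call=False))
            continue
        for c in rrdr:
            rows.append(dict(isolate_id=iso, strain=strain, glucose=glucose,
                             cds_pos=c.cds_pos, kind=c.kind,
                             ref_allele=c.ref_allele, alt_allele=c.alt_allele,
                             codon_number=c.codon_number, aa_change=c.aa_change,
                             cluster=c.cluster, category=_category_for(c),
                             multi_call=flag))
    return pd.DataFrame(rows)


def write_vcf(calls_table: pd.DataFrame, ref: Reference, path) -> None:
    """Write RRDR calls as a minimal VCF 4.2 in genomic coordinates.

    POS = genome_offset + cds_pos - 1; indels are emitted with the
    padding base before the event, VCF style.
    """
    cds = ref.cds_sequence
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.genome_accession}>\n")
        fh.write("##INFO=<ID=ISOLATE,Number=1,Type=String,"
                 'Description="Isolate identifier">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        sub = calls_table[calls_table["category"] != "none_detected"]
        for _, row in sub.iterrows():
            cds_pos = int(row["cds_pos"])
            if row["kind"] == "substitution":
                pos = ref.genome_offset + cds_pos - 1
                ref_a, alt_a = row["ref_allele"], row["alt_allele"]
            elif row["kind"] == "deletion":
                pos = ref.genome_offset + cds_pos - 2
                pad = cds[cds_pos - 2]
                ref_a = pad + row["ref_allele"]
                alt_a = pad
            else:  # insertion after cds_pos
                pos = ref.genome_offset + cds_pos - 1
                pad = cds[cds_pos - 1]
                ref_a = pad
                alt_a = pad + row["alt_allele"]
            fh.write(f"{ref.genome_accession}\t{pos}\t.\t{ref_a}\t{alt_a}"
                     f"\t.\tPASS\tISOLATE={row['isolate_id']}\n")


def load_reference(fasta_path, gene_id: str = "rpoB",
                   genome_accession: str = "NC_000913.3",
                   genome_offset: int = 4181245) -> Reference:
    """Load the CDS reference from a FASTA file (first record)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    return Reference(gene_id=gene_id, cds_sequence=str(record.seq),
                     genome_accession=genome_accession,
                     genome_offset=genome_offset)
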