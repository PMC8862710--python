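"""Readers and writers for the file formats the pipeline touches.

FASTA goes through Biopython.  BLAST tabular (outfmt-6 dialect) and VCF
are 1-based inclusive on disk and converted to the package's 0-based
half-open convention here, at the boundary.  TSV profiles carry their
column documentation and provenance in ``#``-prefixed header comments.
"""

from __future__ import annotations

import io as _io
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentHit, GeneModel, Genome, GenomicInterval, PileupSite

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are upper-cased and maximal N-runs become gap intervals.
    Duplicate record ids and empty files are errors.
    """
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate id in FASTA: {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"empty FASTA file: {path}")
    return Genome.from_sequences(sequences)


def write_fasta(genome_or_sequences, path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    seqs = (
        genome_or_sequences.sequences
        if isinstance(genome_or_sequences, Genome)
        else genome_or_sequences
    )
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_COLS = (
    "qid sid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_hits_tabular(path) -> List[AlignmentHit]:
    """Parse 12-column BLAST tabular hits (organelle query vs nuclear subject).

    On-disk coordinates are 1-based inclusive; reversed subject spans are
    normalized to ``start < end`` with strand ``'-'``.  Normalization is
    idempotent: hits already normalized pass through unchanged.
    """
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric coordinate field ({exc})") from None
            if not 0.0 <= pident <= 100.0:
                raise ValueError(f"line {lineno}: identity out of range ({pident})")
            strand = "+"
            if qstart > qend:
                qstart, qend = qend, qstart
                strand = "-" if strand == "+" else "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-" if strand == "+" else "+"
            hits.append(
                AlignmentHit(
                    source_id=qid,
                    source_start=qstart - 1,
                    source_end=qend,
                    target=GenomicInterval(sid, sstart - 1, send, strand),
                    identity=pident,
                    aln_length=length,
                    evalue=evalue,
                )
            )
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits back to 1-based BLAST tabular (inverse of the reader)."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = h.target.start + 1, h.target.end
            if h.target.strand == "-":
                sstart, send = send, sstart
            mismatch = max(0, round(h.aln_length * (1 - h.identity / 100.0)))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.source_id,
                        h.target.chrom,
                        f"{h.identity:.2f}",
                        h.aln_length,
                        mismatch,
                        0,
                        h.source_start + 1,
                        h.source_end,
                        sstart,
                        send,
                        f"{h.evalue:.2e}",
                        round(2 * h.aln_length, 1),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_regions_bed(regions, path, header_comments: Sequence[str] = ()) -> None:
    """Write BED4/BED6 regions (0-based half-open on disk, like in memory).

    ``regions`` is an iterable of ``(interval, name)`` or
    ``(interval, name, score)`` tuples, or bare intervals.
    """
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"#{c}\n")
        for region in regions:
            if isinstance(region, GenomicInterval):
                iv, name, score = region, ".", None
            elif len(region) == 2:
                (iv, name), score = region, None
            else:
                iv, name, score = region
            cols = [iv.chrom, str(iv.start), str(iv.end), str(name)]
            if score is not None:
                cols += [str(score), iv.strand if iv.strand != "." else "."]
            fh.write("\t".join(cols) + "\n")


def read_regions_bed(path) -> List[Tuple[GenomicInterval, str]]:
    out: List[Tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_genes_gff3(path) -> List[GeneModel]:
    """Read gene models (``gene`` + child ``exon`` features) from GFF3.

    A gene carrying the attribute ``duplication=1`` is flagged as a
    member of a multi-copy family.
    """
    genes: Dict[str, GeneModel] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand if strand in "+-" else ".")
            if ftype == "gene":
                gid = attributes.get("ID", f"{chrom}:{start}-{end}")
                genes[gid] = GeneModel(
                    interval=iv,
                    id=gid,
                    duplication_flag=attributes.get("duplication") == "1",
                )
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append(iv)
    out = []
    for gid, gene in genes.items():
        out.append(
            GeneModel(
                interval=gene.interval,
                id=gid,
                exons=exons.get(gid, []),
                duplication_flag=gene.duplication_flag,
            )
        )
    return out


def write_genes_gff3(genes: Iterable[GeneModel], path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in header_comments:
            fh.write(f"#{c}\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.id}"
            if g.duplication_flag:
                attrs += ";duplication=1"
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(
                f"{iv.chrom}\tgenarch\tgene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chrom}\tgenarch\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )


# ---------------------------------------------------------------------------
# Pileup TSV (chrom, pos, ref, A, C, G, T), 1-based positions on disk


def read_pileup_tsv(path) -> List[PileupSite]:
    sites: List[PileupSite] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, ref, a, c, g, t = line.split("\t")
            sites.append(
                PileupSite(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref_base=ref,
                    counts={"A": int(a), "C": int(c), "G": int(g), "T": int(t)},
                )
            )
    return sites


def write_pileup_tsv(sites: Iterable[PileupSite], path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"#{c}\n")
        fh.write("#chrom\tpos\tref\tA\tC\tG\tT\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.ref_base}\t"
                f"{s.counts['A']}\t{s.counts['C']}\t{s.counts['G']}\t{s.counts['T']}\n"
            )


def read_consensus_tsv(path) -> Dict[Tuple[str, int], str]:
    """Per-site consensus base of a second individual (chrom, 1-based pos, base)."""
    consensus: Dict[Tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, base = line.split("\t")
            consensus[(chrom, int(pos) - 1)] = base.strip()
    return consensus


def write_consensus_tsv(consensus: Dict[Tuple[str, int], str], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tbase\n")
        for (chrom, pos), base in sorted(consensus.items()):
            fh.write(f"{chrom}\t{pos + 1}\t{base}\n")


# ---------------------------------------------------------------------------
# Window-profile TSV


def write_profile_tsv(profile: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> None:
    """Write a per-window profile table with documented columns.

    The frame must carry ``chrom``, ``start``, ``end`` columns; remaining
    columns are window metrics.  Header comments (provenance, column
    docs) are ``#``-prefixed so the file round-trips through the reader.
    """
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"#{c}\n")
        fh.write("#columns: " + "\t".join(profile.columns) + "\n")
        profile.to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 (sites + single-sample GT)

_STATE_TO_GT = {
    "heterozygous": "0/1",
    "homozygous_alt": "1/1",
    "reference": "0/0",
    "no_call": "./.",
}


def write_snp_vcf(calls, path, sample: str = "sample", header_comments: Sequence[str] = ()) -> None:
    """Write SNP calls as a minimal VCF 4.2 with a GT field.

    ``calls`` are :class:`genarch.snp.SnpCall` objects; positions convert
    from 0-based memory to 1-based VCF.  Chromosomes must be known if a
    contig map was given upstream; here the calls themselves define them.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in header_comments:
            fh.write(f"##{c}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for call in calls:
            gt = _STATE_TO_GT[call.state]
            alt = call.alt_base if call.alt_base and call.alt_base != call.ref_base else "."
            fh.write(
                f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref_base}\t{alt}\t.\t"
                f"{'PASS' if call.state != 'no_call' else call.reason}\t.\tGT\t{gt}\n"
            )
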