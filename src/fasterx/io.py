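"""File I/O for the pipeline's plain-text interchange formats.

TSV tables go through pandas; FASTA through Biopython. One FASTA file per
gene (three-species codon alignments, records named ingroup1/ingroup2/
outgroup) or per RAD locus (records named population_individual_allele).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import CodonAlignmentTriple
from .diversity import PopulationLocusAlignment


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _write_fasta(path, names, seqs) -> None:
    records = [
        SeqRecord(Seq(s), id=n, description="") for n, s in zip(names, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_codon_alignments(triples: list[CodonAlignmentTriple], outdir) -> pd.DataFrame:
    """One 3-record FASTA per gene plus the gene-class map table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in triples:
        _write_fasta(
            outdir / f"{t.gene_id}.fasta",
            ["ingroup1", "ingroup2", "outgroup"],
            [t.ingroup1, t.ingroup2, t.outgroup],
        )
        rows.append({"gene_id": t.gene_id, "chrom_class": t.chrom_class})
    return pd.DataFrame(rows)


def read_codon_alignments(indir, class_map: pd.DataFrame) -> list[CodonAlignmentTriple]:
    classes = dict(zip(class_map["gene_id"], class_map["chrom_class"]))
    triples = []
    for gene_id, chrom_class in classes.items():
        recs = {
            r.id: str(r.seq) for r in SeqIO.parse(str(Path(indir) / f"{gene_id}.fasta"), "fasta")
        }
        triples.append(
            CodonAlignmentTriple(
                gene_id=gene_id,
                ingroup1=recs["ingroup1"],
                ingroup2=recs["ingroup2"],
                outgroup=recs["outgroup"],
                chrom_class=chrom_class,
            )
        )
    return triples


def write_rad_loci(loci: list[PopulationLocusAlignment], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for loc in loci:
        _write_fasta(
            outdir / f"{loc.population}__{loc.locus_id}.fasta", loc.names, loc.sequences
        )


def read_rad_loci(indir, locus_map: pd.DataFrame) -> list[PopulationLocusAlignment]:
    loci = []
    for _, row in locus_map.iterrows():
        path = Path(indir) / f"{row['population']}__{row['locus_id']}.fasta"
        recs = list(SeqIO.parse(str(path), "fasta"))
        loci.append(
            PopulationLocusAlignment(
                population=row["population"],
                locus_id=row["locus_id"],
                scaffold_id=row["scaffold_id"],
                position=int(row["position"]),
                chrom_class=row["chrom_class"],
                names=[r.id for r in recs],
                sequences=[str(r.seq) for r in recs],
            )
        )
    return loci
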