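"""McDonald-Kreitman test per chromosome class.

Variants are classified synonymous/nonsynonymous from their CDS context by
comparing the translated reference and alternate codons (stop gain/loss is
"other" and excluded). Alpha, the proportion of substitutions fixed by
adaptive evolution, is 1 - (Ds Pn)/(Dn Ps); negative values indicate
segregating slightly deleterious nonsynonymous variants. No divergence or
low-frequency corrections are applied. Sites both polymorphic and divergent
count in both categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon import translate_codon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MKTable:
    chrom_class: str
    pn: int
    ps: int
    dn: int
    ds: int

    def __post_init__(self):
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValueError("MK counts must be nonnegative")


@dataclass(frozen=True)
class MKResult:
    chrom_class: str
    alpha: float | None
    neutrality_index: float | None


def classify_variant(cds_sequence: str, position: int, alt_base: str) -> str:
    """Classify a single-base change at a 0-based CDS position.

    Returns "synonymous", "nonsynonymous" or "other" (stop gain/loss, or a
    no-op change). Ambiguous reference codons raise ValueError so callers can
    skip the variant with a warning.
    """
    cds = cds_sequence.upper()
    alt_base = alt_base.upper()
    if not 0 <= position < len(cds):
        raise ValueError("position outside CDS")
    if alt_base not in "ACGT":
        raise ValueError(f"invalid alternate base {alt_base!r}")
    ci = position // 3
    ref_codon = cds[3 * ci : 3 * ci + 3]
    if len(ref_codon) < 3:
        raise ValueError("position in an incomplete trailing codon")
    if set(ref_codon) - set("ACGT"):
        raise ValueError(f"ambiguous reference codon {ref_codon!r}")
    off = position % 3
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
    if alt_codon == ref_codon:
        return "other"
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref is None or aa_alt is None:
        return "other"  # stop codon involved
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def mk_alpha(table: MKTable) -> MKResult:
    """Alpha = 1 - (Ds Pn)/(Dn Ps); undefined (None) on zero denominators."""
    if table.ps == 0 or table.dn == 0:
        logger.warning("%s: Ps or Dn is zero; alpha undefined", table.chrom_class)
        return MKResult(table.chrom_class, None, None)
    ni = (table.pn / table.ps) / (table.dn / table.ds) if table.ds else None
    alpha = 1.0 - (table.ds * table.pn) / (table.dn * table.ps)
    return MKResult(table.chrom_class, float(alpha), None if ni is None else float(ni))


def _classify_table(
    variants: pd.DataFrame, annot: pd.DataFrame, genome: dict[str, str], min_cov: int
) -> pd.DataFrame:
    """Attach CDS-context classification to a variant table."""
    if variants.empty:
        return variants.assign(effect=pd.Series(dtype=object), scaffold=pd.Series(dtype=object))
    rows = []
    for _, v in variants.iterrows():
        if "DP" in v and not pd.isna(v["DP"]) and v["DP"] < min_cov:
            continue
        scaf = v["CHROM"]
        pos0 = int(v["POS"]) - 1
        hits = annot[
            (annot["scaffold"] == scaf) & (annot["start"] <= pos0) & (pos0 < annot["end"])
        ]
        if hits.empty:
            continue
        cds_row = hits.iloc[0]
        if cds_row["strand"] != "+":
            raise NotImplementedError("reverse-strand CDS not supported in this dialect")
        cds = genome[scaf][cds_row["start"] : cds_row["end"]]
        cds_pos = pos0 - int(cds_row["start"]) - int(cds_row["frame"])
        if cds_pos < 0:
            continue
        try:
            effect = classify_variant(cds, cds_pos, str(v["ALT"]))
        except ValueError as err:
            logger.warning("skipping variant %s:%s (%s)", scaf, v["POS"], err)
            continue
        rows.append({"scaffold": scaf, "POS": v["POS"], "effect": effect})
    return pd.DataFrame(rows, columns=["scaffold", "POS", "effect"])


def build_mk_tables(
    variants: pd.DataFrame,
    divergences: pd.DataFrame,
    annot: pd.DataFrame,
    genome: dict[str, str],
    class_map: pd.DataFrame,
    min_cov: int = 10,
) -> list[MKTable]:
    """MKTable per chromosome class from polymorphism and divergence tables.

    ``variants``/``divergences`` use a minimal VCF-like dialect (CHROM, POS
    1-based, REF, ALT, DP); variants below ``min_cov`` are excluded
    (divergences carry no coverage filter unless a DP column is present, in
    which case the same rule applies). ``class_map`` maps scaffold -> class
    ("X"/"A"); scaffolds absent from the map are ignored.
    """
    cls = dict(zip(class_map["scaffold_id"], class_map["label"]))
    poly = _classify_table(variants, annot, genome, min_cov)
    div = _classify_table(divergences, annot, genome, min_cov=0)
    out = []
    for chrom_class in ("X", "A"):
        scafs = {s for s, c in cls.items() if c == chrom_class}

        def count(df, effect):
            if df.empty:
                return 0
            sel = df[df["scaffold"].isin(scafs)]
            return int((sel["effect"] == effect).sum())

        out.append(
            MKTable(
                chrom_class=chrom_class,
                pn=count(poly, "nonsynonymous"),
                ps=count(poly, "synonymous"),
                dn=count(div, "nonsynonymous"),
                ds=count(div, "synonymous"),
            )
        )
    return out


def mk_report(tables: list[MKTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        res = mk_alpha(t)
        rows.append(
            {
                "chrom_class": t.chrom_class,
                "Pn": t.pn,
                "Ps": t.ps,
                "Dn": t.dn,
                "Ds": t.ds,
                "alpha": res.alpha,
                "neutrality_index": res.neutrality_index,
            }
        )
    return pd.DataFrame(rows)
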