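"""Strand-aware functional annotation of SNVs against transcript isoforms.

Each (variant, overlapping isoform) pair is placed in exactly one effect
class: ``coding-synonymous``, ``missense``, ``nonsense``, ``stop-loss``,
``intronic``, ``utr5``, ``utr3``, ``noncoding-transcript``; variants
overlapping no transcript get a single ``intergenic`` record.  Coding
effects are decided by rebuilding the affected codon from the spliced CDS
(reverse-complemented for minus-strand genes, rebuilt across an exon
junction when the codon spans one) and translating with the standard
nuclear code.  Protein positions are 1-based and include the initiator
methionine.

Annotation is per isoform, so the same SNV may be, say, missense on one
splice form and 3'-UTR on another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats import GeneModelError, Isoform, SiteKey, VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "EFFECT_CLASSES",
    "CODING_CLASSES",
    "Annotation",
    "ReferenceMismatchError",
    "spliced_cds",
    "validate_cds",
    "classify",
    "annotate_all",
    "write_annotations",
]

EFFECT_CLASSES = (
    "coding-synonymous", "missense", "nonsense", "stop-loss",
    "intronic", "utr5", "utr3", "noncoding-transcript", "intergenic",
)
CODING_CLASSES = ("coding-synonymous", "missense", "nonsense", "stop-loss")

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


class ReferenceMismatchError(ValueError):
    """The reference base at a variant's position differs from its REF allele."""


@dataclass(frozen=True)
class Annotation:
    """Effect of one SNV on one transcript isoform."""

    site_key: SiteKey
    isoform_id: str | None
    gene_symbol: str | None
    effect_class: str
    codon_index: int | None = None  # 1-based protein position
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_coding(self) -> bool:
        return self.effect_class in CODING_CLASSES

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect_class in ("missense", "nonsense", "stop-loss")

    def hgvs_p(self) -> str | None:
        """HGVS-like protein shorthand, e.g. ``p.Lys8Ter``."""
        if not self.is_coding:
            return None
        return f"p.{_AA3[self.ref_aa]}{self.codon_index}{_AA3[self.alt_aa]}"


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence [start, end), accepting pyfaidx or plain dicts."""
    try:
        seq = reference[chrom]
    except KeyError:
        seq = reference["chr" + chrom]
    piece = seq[start:end]
    return str(getattr(piece, "seq", piece)).upper()


def spliced_cds(isoform: Isoform, reference) -> str:
    """The isoform's coding sequence, spliced and in transcript orientation.

    Exonic CDS segments are concatenated in genomic order and
    reverse-complemented for minus-strand models, so the result runs
    5'->3' starting at the initiator codon.
    """
    if not isoform.is_coding:
        raise GeneModelError(f"{isoform.isoform_id}: noncoding model has no CDS")
    seq = "".join(_fetch(reference, isoform.chrom, s, e) for s, e in isoform.cds_intervals())
    if isoform.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def validate_cds(isoform: Isoform, reference) -> bool:
    """True if the model's CDS length is a multiple of 3 (translatable)."""
    if not isoform.is_coding:
        return False
    return isoform.cds_len % 3 == 0


def _cds_offset(isoform: Isoform, pos0: int) -> int | None:
    """0-based offset of genomic pos0 within the spliced CDS, or None if non-CDS."""
    genomic_off = 0
    hit = None
    for s, e in isoform.cds_intervals():
        if s <= pos0 < e:
            hit = genomic_off + (pos0 - s)
            break
        genomic_off += e - s
    if hit is None:
        return None
    if isoform.strand == "+":
        return hit
    return isoform.cds_len - 1 - hit


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify(site: VariantSite, isoform: Isoform, reference,
             cds_cache: dict[str, str] | None = None) -> Annotation:
    """Classify one SNV against one overlapping isoform.

    The variant's position is mapped to UTR / intron / CDS; within the CDS
    the containing codon is rebuilt from the spliced coding sequence and
    both alleles translated.  Raises :class:`ReferenceMismatchError` when
    the reference base at the site disagrees with the variant's REF.
    """
    pos0 = site.pos - 1
    if not (isoform.tx_start <= pos0 < isoform.tx_end):
        raise ValueError(f"{site.chrom}:{site.pos} does not overlap {isoform.isoform_id}")
    ref_base = _fetch(reference, site.chrom, pos0, pos0 + 1)
    if ref_base != site.ref:
        raise ReferenceMismatchError(
            f"reference has {ref_base} at {site.chrom}:{site.pos}, variant REF is {site.ref}"
        )

    def ann(effect: str, **kw) -> Annotation:
        return Annotation(site_key=site.key, isoform_id=isoform.isoform_id,
                          gene_symbol=isoform.gene_symbol, effect_class=effect, **kw)

    in_exon = any(s <= pos0 < e for s, e in isoform.exons)
    if not in_exon:
        return ann("intronic")
    if not isoform.is_coding:
        return ann("noncoding-transcript")
    if pos0 < isoform.cds_start:
        return ann("utr5" if isoform.strand == "+" else "utr3")
    if pos0 >= isoform.cds_end:
        return ann("utr3" if isoform.strand == "+" else "utr5")

    cds_idx = _cds_offset(isoform, pos0)
    assert cds_idx is not None
    if cds_cache is not None and isoform.isoform_id in cds_cache:
        cds = cds_cache[isoform.isoform_id]
    else:
        cds = spliced_cds(isoform, reference)
        if cds_cache is not None:
            cds_cache[isoform.isoform_id] = cds
    if len(cds) % 3 != 0:
        raise GeneModelError(f"{isoform.isoform_id}: CDS length {len(cds)} not divisible by 3")

    codon_i, within = divmod(cds_idx, 3)
    ref_codon = cds[codon_i * 3: codon_i * 3 + 3]
    if isoform.strand == "+":
        tx_ref, tx_alt = site.ref, site.alt
    else:
        tx_ref = site.ref.translate(_COMPLEMENT)
        tx_alt = site.alt.translate(_COMPLEMENT)
    assert ref_codon[within] == tx_ref
    alt_codon = ref_codon[:within] + tx_alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        effect = "coding-synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == "*":
        effect = "stop-loss"
    else:
        effect = "missense"
    return ann(effect, codon_index=codon_i + 1, ref_codon=ref_codon,
               alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa)


def annotate_all(sites: Iterable[VariantSite], isoforms: Sequence[Isoform],
                 reference) -> list[Annotation]:
    """Annotate every site against every overlapping isoform.

    Yields one record per (site, overlapping isoform) pair; sites touching
    no transcript get a single intergenic record.  Isoforms whose CDS
    length is not a multiple of 3 are excluded from annotation and logged.
    Output order is (chrom, pos, alt, isoform_id).
    """
    usable: list[Isoform] = []
    for iso in isoforms:
        if iso.is_coding and iso.cds_len % 3 != 0:
            log.warning("excluding %s: CDS length %d not divisible by 3",
                        iso.isoform_id, iso.cds_len)
            continue
        usable.append(iso)
    trees: dict[str, IntervalTree] = {}
    for i, iso in enumerate(usable):
        trees.setdefault(iso.chrom, IntervalTree()).addi(iso.tx_start, iso.tx_end, i)
    cds_cache: dict[str, str] = {}
    out: list[Annotation] = []
    for site in sorted(sites, key=lambda v: (v.chrom, v.pos, v.alt)):
        tree = trees.get(site.chrom)
        hits = sorted(tree[site.pos - 1], key=lambda iv: usable[iv.data].isoform_id) if tree else []
        if not hits:
            out.append(Annotation(site_key=site.key, isoform_id=None,
                                  gene_symbol=None, effect_class="intergenic"))
            continue
        for iv in hits:
            out.append(classify(site, usable[iv.data], reference, cds_cache))
    return out


def write_annotations(path: str, annotations: Sequence[Annotation]) -> None:
    """Write annotations as a TSV: site key, isoform, class, protein change."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\talt\tgene\tisoform\teffect\tprotein_change\n")
        for a in annotations:
            fh.write("\t".join([
                a.site_key.chrom, str(a.site_key.pos), a.site_key.alt,
                a.gene_symbol or ".", a.isoform_id or ".",
                a.effect_class, a.hgvs_p() or ".",
            ]) + "\n")
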