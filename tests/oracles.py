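"""Independent brute-force oracles and toy-data builders shared by the tests.

Everything here is deliberately naive (per-base scans, all-windows
enumeration, whole-protein rebuilds) and independent of the library code
paths it is used to check.
"""

from __future__ import annotations

from Bio.Seq import Seq

from exoscreen.formats import Isoform

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def window_failures(positions, window_bp=10, max_snps=2):
    """Brute force: positions failing the clustering rule, trying every window.

    Every window start that could matter is one containing at least one
    site; windows holding no site trivially cannot violate the rule, so
    enumerating starts in [p - window_bp + 1, p] for every site p is
    exhaustive.
    """
    import bisect
    pos = sorted(set(positions))
    bad = set()
    starts = {s for p in pos for s in range(p - window_bp + 1, p + 1)}
    for start in starts:
        lo = bisect.bisect_left(pos, start)
        hi = bisect.bisect_right(pos, start + window_bp - 1)
        if hi - lo > max_snps:
            bad.update(pos[lo:hi])
    return bad


def per_base_membership(pos0, intervals):
    """True if 0-based position lies in any (start, end) half-open interval."""
    return any(s <= pos0 < e for s, e in intervals)


def venn_cells(sets):
    """Membership-vector tally over the union of named sets."""
    cells = {}
    union = set().union(*sets.values()) if sets else set()
    for key in union:
        vec = frozenset(name for name, s in sets.items() if key in s)
        cells[vec] = cells.get(vec, 0) + 1
    return cells


def toy_gene(cds, strand="+", utr5="ACGTACGTACGT", utr3="TTGGCCAATTGG",
             exon_cuts=(), intron_len=30, offset=50, chrom="1",
             gene="TOY", isoform_id="NM_TOY1"):
    """Hand-buildable single-gene reference + isoform model.

    ``cds`` is given in transcript orientation (starts ATG, ends with a
    stop).  ``exon_cuts`` are transcript indices at which to split exons;
    introns of ``intron_len`` bases are inserted between them.  For minus
    strand the genomic region is the reverse complement and coordinates
    are mirrored.  Returns ({chrom: sequence}, Isoform).
    """
    tx = utr5 + cds + utr3
    bounds = [0, *sorted(exon_cuts), len(tx)]
    pieces, exons_sense, cursor = [], [], 0
    for i in range(len(bounds) - 1):
        piece = tx[bounds[i]:bounds[i + 1]]
        pieces.append(piece)
        exons_sense.append((cursor, cursor + len(piece)))
        cursor += len(piece)
        if i < len(bounds) - 2:
            pieces.append("G" * intron_len)
            cursor += intron_len
    region = "".join(pieces)

    def sense_coord(tx_idx):
        off = tx_idx
        for s, e in exons_sense:
            if off < e - s:
                return s + off
            off -= e - s
        raise IndexError(tx_idx)

    cds_s = sense_coord(len(utr5))
    cds_e = sense_coord(len(utr5) + len(cds) - 1) + 1
    exons = exons_sense
    if strand == "-":
        L = len(region)
        region = str(Seq(region).reverse_complement())
        exons = sorted((L - e, L - s) for s, e in exons_sense)
        cds_s, cds_e = L - cds_e, L - cds_s
    seq = "T" * offset + region + "T" * offset
    iso = Isoform(isoform_id=isoform_id, gene_symbol=gene, chrom=chrom,
                  strand=strand,
                  exons=tuple((s + offset, e + offset) for s, e in exons),
                  cds_start=cds_s + offset, cds_end=cds_e + offset)
    return {chrom: seq}, iso


def spliced_cds_oracle(iso, reference):
    """Independent CDS splice: per-base collection then strand flip."""
    seq = reference[iso.chrom]
    bases = [seq[p] for s, e in iso.exons for p in range(s, e)
             if iso.cds_start <= p < iso.cds_end]
    cds = "".join(bases)
    if iso.strand == "-":
        cds = cds[::-1].translate(COMPLEMENT)
    return cds


def whole_protein_effect(iso, reference, pos0, alt):
    """Effect class by rebuilding and translating the full ref and alt proteins."""
    seq = reference[iso.chrom]
    mutated = {iso.chrom: seq[:pos0] + alt + seq[pos0 + 1:]}
    ref_cds = spliced_cds_oracle(iso, reference)
    alt_cds = spliced_cds_oracle(iso, mutated)
    if ref_cds == alt_cds:
        raise AssertionError("variant does not touch the CDS")
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    diffs = [(i, a, b) for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return "coding-synonymous", None
    assert len(diffs) == 1
    i, a, b = diffs[0]
    if b == "*":
        return "nonsense", i + 1
    if a == "*":
        return "stop-loss", i + 1
    return "missense", i + 1
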