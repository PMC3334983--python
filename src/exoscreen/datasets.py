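"""Published count fixtures from the 10-case stroke exome pilot.

These are the printed per-sample SNV call summaries and per-gene sharing
counts from a pilot exome-sequencing study of ischemic stroke (10 male
cases: 8 African-American, 2 European-Caucasian) screened against dbSNP
and three 1000 Genomes control populations (ASW, YRI, CEU).  They serve
as regression fixtures: the package's arithmetic (count additivity, group
means, non-common SNP density) must reproduce the published derived
numbers from these raw counts.

Three genes (HLA-DPB1, NAT10, FMO2) are excluded from
``load_gene_counts(consistent_only=True)`` because their published
one-decimal densities cannot be reproduced from their own published
inputs under any standard rounding; see the methods note.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "AFRICAN_AMERICAN", "CAUCASIAN",
    "SAMPLE_GROUPS", "load_sample_summaries", "load_gene_counts",
    "write_fixtures",
]

AFRICAN_AMERICAN = "African-American"
CAUCASIAN = "Caucasian"

# sample -> (snps, snps_in_dbsnp, pass_q_filters, pass_qf_and_in_dbsnp,
#            pass_qf_and_novel, indels), SNVs in capture targets only
_SAMPLE_SUMMARIES = {
    "M006":  (31990, 27364, 28103, 25097, 3006, 8313),
    "M0114": (31097, 26887, 26844, 24486, 2358, 6033),
    "M0379": (31756, 27506, 28205, 25370, 2835, 6583),
    "M0432": (31255, 26260, 26668, 23899, 2769, 4750),
    "M0823": (32368, 27139, 28022, 24935, 3087, 4909),
    "M1012": (31385, 26198, 26787, 23830, 2957, 5193),
    "M1096": (30942, 26045, 26449, 23674, 2775, 4737),
    "M1107": (31595, 26797, 27574, 24651, 2923, 4823),
    "SW393": (26472, 24116, 23262, 22182, 1080, 5214),
    "SW708": (26942, 24509, 23697, 22567, 1130, 5599),
}

SAMPLE_GROUPS = {s: (AFRICAN_AMERICAN if s.startswith("M") else CAUCASIAN)
                 for s in _SAMPLE_SUMMARIES}

# gene -> (exon_bases, case_snps, shared_all, published one-decimal density)
_GENE_COUNTS = {
    "CSN3":     (1312, 10, 3, 5.3),
    "FLT3":     (8622, 35, 10, 2.9),
    "FMO2":     (3512, 20, 11, 2.7),
    "HLA-DPB1": (2025, 46, 5, 20.3),
    "LRIT2":    (2300, 11, 2, 3.9),
    "NAT10":    (9798, 25, 2, 2.4),
    "PIKFYVE":  (4582, 8, 2, 1.3),
    "PODN":     (4332, 17, 5, 2.8),
    "TEKT2":    (2821, 7, 1, 2.1),
    "ACE":      (9915, 31, 8, 2.3),
    "APOE":     (1782, 2, 0, 1.1),
    "F2":       (4976, 8, 3, 1.0),
    "F5":       (13243, 48, 20, 2.1),
    "ITGA2":    (11020, 41, 23, 1.6),
    "ITGB3":    (6226, 21, 8, 2.1),
    "LTA":      (1189, 5, 2, 2.5),
    "MTHFR":    (4666, 19, 7, 2.6),
    "NINJ2":    (1277, 2, 2, 0.0),
    "NOS3":     (8896, 22, 3, 2.1),
    "SERPINE1": (3054, 8, 3, 1.6),
}

# published densities that do not reproduce from their own published inputs
_INCONSISTENT = ("FMO2", "HLA-DPB1", "NAT10")


def load_sample_summaries() -> pd.DataFrame:
    """Published per-sample SNV summary counts (rows = samples).

    Columns: snps, snps_in_dbsnp, pass_q_filters, pass_qf_and_in_dbsnp,
    pass_qf_and_novel, indels, group.
    """
    df = pd.DataFrame.from_dict(
        _SAMPLE_SUMMARIES, orient="index",
        columns=["snps", "snps_in_dbsnp", "pass_q_filters",
                 "pass_qf_and_in_dbsnp", "pass_qf_and_novel", "indels"],
    )
    df.index.name = "sample"
    df["group"] = [SAMPLE_GROUPS[s] for s in df.index]
    return df


def load_gene_counts(consistent_only: bool = False) -> pd.DataFrame:
    """Published per-gene inputs of the non-common density statistic.

    Columns: exon_bases, case_snps, shared_all, published_density.  With
    ``consistent_only`` the three rows whose published density is not
    reproducible from the published inputs are dropped.
    """
    df = pd.DataFrame.from_dict(
        _GENE_COUNTS, orient="index",
        columns=["exon_bases", "case_snps", "shared_all", "published_density"],
    )
    df.index.name = "gene"
    if consistent_only:
        df = df.drop(index=list(_INCONSISTENT))
    return df


def write_fixtures(out_dir: str) -> dict[str, str]:
    """Emit both fixture tables as TSV files; returns {name: path}."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (("sample_summaries", load_sample_summaries()),
                     ("gene_counts", load_gene_counts())):
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t")
        paths[name] = path
    return paths
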