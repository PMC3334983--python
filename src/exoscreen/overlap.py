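"""Variant sharing between the case pool and control-population catalogs.

The case "pool" is the union of site keys over all case samples — not
unique-per-sample counts, but variants appearing at least once in any
individual.  Sharing is computed set-wise on (chrom, pos, alt) keys
against control catalogs (e.g. 1000 Genomes ASW / YRI / CEU site lists)
and a dbSNP stand-in for novelty.

"Non-common" variants of a gene are its case variants minus those shared
simultaneously by the cases and ALL control populations (the all-way
intersection); an alternative reading — minus the union of the controls —
is available via ``mode="union"``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import PopulationCatalog, SiteKey

__all__ = [
    "OverlapReport",
    "case_pool",
    "venn_partition",
    "overlap_report",
    "split_novel",
    "non_common_set",
]


@dataclass
class OverlapReport:
    """All intersection sizes between the case pool and k control catalogs.

    ``partition`` maps a frozenset of set names (the exact-membership
    pattern) to the number of keys belonging to exactly those sets; its
    cells are disjoint and sum to the size of the union.
    """

    set_names: list[str]
    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    three_way: dict[tuple[str, str, str], int]
    shared_all: int
    case_only: int
    partition: dict[frozenset, int] = field(default_factory=dict)

    def intersection_size(self, names: Sequence[str]) -> int:
        """Size of the plain intersection of the named sets (from the partition)."""
        req = set(names)
        return sum(n for cell, n in self.partition.items() if req <= cell)

    def to_dict(self) -> dict:
        return {
            "set_sizes": dict(self.set_sizes),
            "pairwise": {" & ".join(k): v for k, v in self.pairwise.items()},
            "three_way": {" & ".join(k): v for k, v in self.three_way.items()},
            "shared_all": self.shared_all,
            "case_only": self.case_only,
            "partition": {" & ".join(sorted(cell)): n for cell, n in self.partition.items()},
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_row_tsv(self, path: str) -> None:
        """One-row TSV of set sizes, pairwise/3-way intersections, shared-all."""
        cols = {f"{n}_snps": self.set_sizes[n] for n in self.set_names}
        cols.update({"shared_" + "_".join(k): v for k, v in self.pairwise.items()})
        cols.update({"shared_" + "_".join(k): v for k, v in self.three_way.items()})
        cols["shared_all"] = self.shared_all
        cols["case_only"] = self.case_only
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            fh.write("\t".join(str(v) for v in cols.values()) + "\n")


def case_pool(sites_by_sample: Mapping[str, Iterable]) -> set[SiteKey]:
    """Union of site keys over all case samples.

    Accepts per-sample iterables of either :class:`SiteKey` or objects with
    a ``key`` attribute (e.g. :class:`~exoscreen.formats.VariantSite`).
    """
    pool: set[SiteKey] = set()
    for sites in sites_by_sample.values():
        for s in sites:
            pool.add(s if isinstance(s, SiteKey) else s.key)
    return pool


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact-membership partition of the union of named sets.

    Returns {frozenset(names the key belongs to): count}; only non-empty
    cells appear.
    """
    cells: dict[frozenset, int] = {}
    union: set = set().union(*sets.values()) if sets else set()
    for key in union:
        cell = frozenset(name for name, s in sets.items() if key in s)
        cells[cell] = cells.get(cell, 0) + 1
    return cells


def overlap_report(pool: set[SiteKey], catalogs: Sequence[PopulationCatalog],
                   case_name: str = "cases") -> OverlapReport:
    """Compute all sharing statistics between the case pool and the catalogs."""
    if not catalogs:
        raise ValueError("at least one control catalog is required")
    sets: dict[str, set] = {case_name: set(pool)}
    for cat in catalogs:
        sets[cat.name] = set(cat.sites)
    names = list(sets)
    partition = venn_partition(sets)

    def isect(group: Sequence[str]) -> int:
        req = set(group)
        return sum(n for cell, n in partition.items() if req <= cell)

    return OverlapReport(
        set_names=names,
        set_sizes={n: len(s) for n, s in sets.items()},
        pairwise={pair: isect(pair) for pair in itertools.combinations(names, 2)},
        three_way={trip: isect(trip) for trip in itertools.combinations(names, 3)},
        shared_all=isect(names),
        case_only=partition.get(frozenset([case_name]), 0),
        partition=partition,
    )


def split_novel(case_sites: Iterable[SiteKey], dbsnp: PopulationCatalog,
                ) -> tuple[set[SiteKey], set[SiteKey]]:
    """Partition case site keys into (known, novel) against the dbSNP stand-in."""
    keys = {s if isinstance(s, SiteKey) else s.key for s in case_sites}
    known = {k for k in keys if k in dbsnp}
    return known, keys - known


def non_common_set(case_gene_sites: Iterable[SiteKey],
                   catalogs: Sequence[PopulationCatalog],
                   mode: str = "shared_all") -> set[SiteKey]:
    """Case variants of a gene that are not common to all populations.

    ``mode="shared_all"`` (default) removes only the sites present in every
    control catalog simultaneously — a site shared with some but not all
    controls stays non-common.  ``mode="union"`` removes any site present
    in at least one control catalog.
    """
    keys = {s if isinstance(s, SiteKey) else s.key for s in case_gene_sites}
    if not catalogs:
        return keys
    if mode == "shared_all":
        common = set(catalogs[0].sites)
        for cat in catalogs[1:]:
            common &= cat.sites
    elif mode == "union":
        common = set().union(*(cat.sites for cat in catalogs))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return keys - common
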