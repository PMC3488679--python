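"""Host-photobiont association, guild structure and the geographic mosaic.

The qualitative pattern "higher selectivity locally than globally" is made
quantitative here through the mosaic ratio

    m(s) = mean over sampled regions r of k(s, r) / k(s)

where k(s, r) is the number of distinct photobiont genotypes a fungal species
s associates with in region r and k(s) its global genotype richness.  Strong
regional founder structure pushes m(s) far below what region-shuffled data
produce; the permutation null shuffles region labels within species, which
preserves per-species specimen counts and per-region totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .seq_io import SpecimenRecord

#: region cells with fewer specimens than this are flagged as thin support
#: and excluded from the mosaic ratio by default
DEFAULT_THIN_SUPPORT = 2


class SelectivityError(ValueError):
    pass


@dataclass
class AssociationTable:
    """Cross-tabulation of paired specimens: (species, region, genotype) -> count."""

    counts: pd.DataFrame  # columns: species, region, genotype, count
    n_paired_used: int
    n_unpaired_excluded: int

    def cell(self, species: str, region: str) -> dict[str, int]:
        sub = self.counts[
            (self.counts.species == species) & (self.counts.region == region)
        ]
        return dict(zip(sub.genotype, sub["count"]))

    @property
    def species(self) -> list[str]:
        return sorted(self.counts.species.unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.counts.region.unique())


@dataclass
class SelectivityProfile:
    species: str
    k_global: int
    k_regional: dict[str, int]
    mosaic_ratio: float
    thin_regions: list[str] = field(default_factory=list)
    sharing_partners: set[str] = field(default_factory=set)


def build_association(
    records: Iterable[SpecimenRecord],
    genotype_of_seq: dict[str, str],
) -> AssociationTable:
    """Cross-tabulate paired specimens by species, region and photobiont
    genotype.  Unpaired records are excluded (count reported); a paired record
    whose photobiont sequence resolves to no genotype is an error."""
    rows = []
    n_unpaired = 0
    for rec in records:
        if not rec.is_paired:
            n_unpaired += 1
            continue
        if rec.photobiont_seq_id not in genotype_of_seq:
            raise SelectivityError(
                f"specimen {rec.specimen_id!r}: photobiont sequence "
                f"{rec.photobiont_seq_id!r} resolves to no known genotype"
            )
        rows.append(
            (rec.fungal_species, rec.region, genotype_of_seq[rec.photobiont_seq_id])
        )
    if rows:
        df = (
            pd.DataFrame(rows, columns=["species", "region", "genotype"])
            .groupby(["species", "region", "genotype"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
    else:
        df = pd.DataFrame(columns=["species", "region", "genotype", "count"])
    return AssociationTable(counts=df, n_paired_used=len(rows),
                            n_unpaired_excluded=n_unpaired)


def _mosaic_ratio(regional_sets: dict[str, set[str]], k_global: int) -> float:
    if k_global == 0 or not regional_sets:
        return float("nan")
    return float(np.mean([len(g) / k_global for g in regional_sets.values()]))


def selectivity_profiles(
    table: AssociationTable,
    thin_support: int = DEFAULT_THIN_SUPPORT,
) -> list[SelectivityProfile]:
    """Per-species regional and global genotype richness and mosaic ratio.

    Regions with fewer than ``thin_support`` specimens of a species are
    flagged and excluded from that species' mosaic ratio (single-specimen
    cells make richness ratios degenerate).
    """
    df = table.counts
    profiles = []
    shared = sharing_graph(table)
    for sp in table.species:
        sub = df[df.species == sp]
        k_global = sub.genotype.nunique()
        k_regional: dict[str, int] = {}
        thin: list[str] = []
        supported: dict[str, set[str]] = {}
        for region, rsub in sub.groupby("region"):
            k_regional[region] = rsub.genotype.nunique()
            if rsub["count"].sum() < thin_support:
                thin.append(region)
            else:
                supported[region] = set(rsub.genotype)
        profiles.append(
            SelectivityProfile(
                species=sp,
                k_global=k_global,
                k_regional=k_regional,
                mosaic_ratio=_mosaic_ratio(supported, k_global),
                thin_regions=sorted(thin),
                sharing_partners=set(shared.projection.neighbors(sp))
                if sp in shared.projection
                else set(),
            )
        )
    return profiles


@dataclass
class SharingGraph:
    bipartite: nx.Graph  # fungal species x genotype codes
    projection: nx.Graph  # species x species, weight = number shared
    flags: pd.DataFrame  # species, shares_with_other, single_genotype


def sharing_graph(table: AssociationTable) -> SharingGraph:
    """Photobiont sharing among fungal species (guild structure)."""
    b = nx.Graph()
    df = table.counts
    for sp in table.species:
        b.add_node(sp, bipartite=0)
    for _, row in df.iterrows():
        b.add_node(row.genotype, bipartite=1)
        if b.has_edge(row.species, row.genotype):
            b[row.species][row.genotype]["weight"] += int(row["count"])
        else:
            b.add_edge(row.species, row.genotype, weight=int(row["count"]))
    proj = nx.Graph()
    proj.add_nodes_from(table.species)
    for g in [n for n, d in b.nodes(data=True) if d.get("bipartite") == 1]:
        hosts = sorted(b.neighbors(g))
        for i, s in enumerate(hosts):
            for t in hosts[i + 1 :]:
                if proj.has_edge(s, t):
                    proj[s][t]["weight"] += 1
                else:
                    proj.add_edge(s, t, weight=1)
    flags = pd.DataFrame(
        {
            "species": table.species,
            "shares_with_other": [proj.degree(s) > 0 for s in table.species],
            "single_genotype": [
                df[df.species == s].genotype.nunique() == 1 for s in table.species
            ],
        }
    )
    return SharingGraph(bipartite=b, projection=proj, flags=flags)


@dataclass
class MosaicTest:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_permutations: int
    per_species: pd.DataFrame  # species, observed m, p, BH-adjusted p


def _mean_mosaic(df: pd.DataFrame, thin_support: int) -> tuple[float, dict[str, float]]:
    per_species: dict[str, float] = {}
    for sp, sub in df.groupby("species"):
        k_global = sub.genotype.nunique()
        ratios = []
        for _, rsub in sub.groupby("region"):
            if len(rsub) >= thin_support:
                ratios.append(rsub.genotype.nunique() / k_global)
        if ratios and k_global:
            per_species[sp] = float(np.mean(ratios))
    vals = list(per_species.values())
    return (float(np.mean(vals)) if vals else float("nan")), per_species


def mosaic_permutation_test(
    table: AssociationTable,
    n_permutations: int = 1000,
    seed: int = 0,
    thin_support: int = DEFAULT_THIN_SUPPORT,
) -> MosaicTest:
    """Permutation test of the geographic-mosaic contrast.

    Region labels are shuffled within each species (preserving per-species
    specimen counts and per-region totals); the one-sided p-value is the
    fraction of permutations whose mean mosaic ratio is <= the observed one
    (add-one smoothed).  Per-species p-values are reported raw and after
    Benjamini-Hochberg adjustment.
    """
    rng = np.random.default_rng(seed)
    df = table.counts.loc[
        table.counts.index.repeat(table.counts["count"])
    ].reset_index(drop=True)[["species", "region", "genotype"]]
    obs_mean, obs_per_sp = _mean_mosaic(df, thin_support)
    null_means = np.empty(n_permutations)
    null_per_sp: dict[str, list[float]] = {sp: [] for sp in obs_per_sp}
    species_groups = {sp: sub.index.to_numpy() for sp, sub in df.groupby("species")}
    regions = df.region.to_numpy()
    for b in range(n_permutations):
        perm_regions = regions.copy()
        for idx in species_groups.values():
            perm_regions[idx] = rng.permutation(perm_regions[idx])
        pdf = df.assign(region=perm_regions)
        null_means[b], per_sp = _mean_mosaic(pdf, thin_support)
        for sp, v in per_sp.items():
            if sp in null_per_sp:
                null_per_sp[sp].append(v)
    p = (1 + np.sum(null_means <= obs_mean + 1e-12)) / (1 + n_permutations)
    sp_rows = []
    for sp, m in sorted(obs_per_sp.items()):
        nulls = np.asarray(null_per_sp[sp])
        p_sp = (1 + np.sum(nulls <= m + 1e-12)) / (1 + len(nulls)) if len(nulls) else np.nan
        sp_rows.append({"species": sp, "mosaic_ratio": m, "p_raw": p_sp})
    per_species = pd.DataFrame(sp_rows)
    if not per_species.empty:
        per_species["p_bh"] = _benjamini_hochberg(per_species.p_raw.to_numpy())
    return MosaicTest(
        observed_mean=obs_mean,
        null_means=null_means,
        p_value=float(p),
        n_permutations=n_permutations,
        per_species=per_species,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def long_range_consistency(
    table_records: Iterable[SpecimenRecord],
    fungal_genotype_of_seq: dict[str, str],
    nostoc_genotype_of_seq: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symbiont combinations maintained across regions.

    Returns (pair-level, genotype-level) tables: every (fungal genotype,
    photobiont genotype) pair observed in >= 2 regions with its region set,
    and every photobiont genotype spanning >= 2 regions.
    """
    pair_regions: dict[tuple[str, str], set[str]] = {}
    geno_regions: dict[str, set[str]] = {}
    for rec in table_records:
        ng = nostoc_genotype_of_seq.get(rec.photobiont_seq_id or "")
        if ng is not None:
            geno_regions.setdefault(ng, set()).add(rec.region)
        fg = fungal_genotype_of_seq.get(rec.fungal_seq_id or "")
        if fg is not None and ng is not None:
            pair_regions.setdefault((fg, ng), set()).add(rec.region)
    pairs = pd.DataFrame(
        [
            {"fungal_genotype": f, "nostoc_genotype": n,
             "n_regions": len(r), "regions": ",".join(sorted(r))}
            for (f, n), r in sorted(pair_regions.items())
            if len(r) >= 2
        ],
        columns=["fungal_genotype", "nostoc_genotype", "n_regions", "regions"],
    )
    genos = pd.DataFrame(
        [
            {"nostoc_genotype": n, "n_regions": len(r), "regions": ",".join(sorted(r))}
            for n, r in sorted(geno_regions.items())
            if len(r) >= 2
        ],
        columns=["nostoc_genotype", "n_regions", "regions"],
    )
    return pairs, genos
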