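"""Synthetic dataset generator with full ground truth.

Emulates the statistical structure of a global cyanolichen symbiont survey:

* tRNA-Leu (UAA) intron sequences (270-365 bp) whose length variation is
  concentrated in the P6b stem loop — degenerate heptanucleotide repeat arms
  folding into a hairpin, per-subgroup non-repeat indel elements, and
  lineage-diagnostic signature characters (3T / 71T / AGTCTTM);
* fungal ITS amplicons (planted ITS of 485-515 bp) wrapped in the conserved
  rns / rnl flank motifs, with species-level and within-species divergence;
* regionally skewed (founder-effect) sampling of fungus x photobiont
  combinations: per-region genotype frequencies are Dirichlet draws around
  each species' global frequencies, with a concentration parameter — low
  concentration means each region is dominated by few genotypes.

Genotypes are derived from per-subgroup templates by sequential branching:
each genotype copies its parent and receives repeat slippage (whole 7-mer
units only) and point substitutions.  Everything is driven by one seeded RNG;
identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import iupac
from .fungal_its import FLANK5_MOTIF
from .intron_annotator import (
    BIPARTITE_TYPE,
    CLASS1,
    CLASS2,
    TRIPARTITE_TYPE,
    ReferenceProfile,
)
from .seq_io import SequenceSet, SpecimenRecord

# fixed conserved segments of the intron template (anchor-free, see tests)
CORE5 = "GGTGTGTTTAAACACGCGTGGCCCGCCTATAGAGACTGCACTCTACAATACTCCTT"
SPACER = "TGTCCTGCAGGTGTTACACG"
CORE3 = "AGGATTGTCGGACATCGCCCTGGACGCCACCTGCAGCTCG"
P5B_ARM = "CTGGTC"

#: P5b terminal loops; base 1 of the loop is the site mapped to reference
#: coordinate 71 (profile offset 14 = 8 nt anchor + 6 nt arm)
P5B_LOOP_BIPARTITE = "TGCA"
P5B_LOOP_TRIPARTITE = "AGCA"

#: P6b central loops; base 3 is T in the bipartite lineage, tripartite
#: lineages carry the AGTCTTM motif (M resolved per genotype)
CENTRAL_LOOP_BIPARTITE = "CCTCCCC"
CENTRAL_LOOP_TRIPARTITE = "AGTCTTM"

ITS_FLANK3_VARIANTS = ("GTTGACCTCGGATCAGGTAGG", "ATTGACCTCGGATCAGGTAGG")

_MAX_RETRIES = 50


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SubgroupSpec:
    """Template of one P6b-defined subgroup."""

    key: str
    lineage: str
    repeat_class: str
    indel_tags: tuple[str, ...]
    base_repeats_per_arm: int
    n_genotypes: int


def default_subgroups() -> tuple[SubgroupSpec, ...]:
    """Seven indel-defined bipartite subgroups plus five Class 1 and four
    Class 2 tripartite subgroups (40 genotypes in total)."""
    bi = [
        ("bi0", (), 10, 7),
        ("bi1", ("*",), 9, 6),
        ("bi2", ("**",), 10, 4),
        ("bi3", ("***",), 9, 4),
        ("bi4", ("^^",), 10, 3),
        ("bi5", ("*", "**"), 9, 2),
        ("bi6", ("***", "^^"), 9, 2),
    ]
    y = [
        ("y0", (), 10, 2),
        ("y1", ("*",), 9, 2),
        ("y2", ("**",), 10, 1),
        ("y3", ("***",), 9, 1),
        ("y4", ("^^",), 10, 1),
    ]
    x = [
        ("x0", (), 9, 2),
        ("x1", ("*",), 10, 1),
        ("x2", ("**",), 9, 1),
        ("x3", ("^^",), 10, 1),
    ]
    out = [SubgroupSpec(k, BIPARTITE_TYPE, CLASS1, t, r, n) for k, t, r, n in bi]
    out += [SubgroupSpec(k, TRIPARTITE_TYPE, CLASS1, t, r, n) for k, t, r, n in y]
    out += [SubgroupSpec(k, TRIPARTITE_TYPE, CLASS2, t, r, n) for k, t, r, n in x]
    return tuple(out)


DEFAULT_SPECIES = (
    "N. bellum",
    "N. parile",
    "N. resupinatum",
    "N. helveticum",
    "N. laevigatum",
    "N. tangeriense",
    "N. washingtoniense",
    "N. cellulosum",
    "N. squamigerum",
    "N. arcticum",
)

DEFAULT_REGIONS = ("Europe", "Asia", "western North America", "eastern North America")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    seed: int = 7
    species_names: tuple[str, ...] = DEFAULT_SPECIES
    tripartite_species: tuple[str, ...] = ("N. arcticum",)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    subgroups: tuple[SubgroupSpec, ...] = field(default_factory=default_subgroups)
    # intron genotype-branching processes
    branch_substitutions: float = 2.0  # mean substitutions per branching step
    branch_slippage_rate: float = 0.4  # prob of a +-1 repeat-unit slip per step
    # per-copy noise on emitted member sequences (curated Sanger data: tiny)
    member_mutation_rate: float = 1e-4
    member_slippage_rate: float = 0.0
    intron_length_bounds: tuple[int, int] = (270, 365)
    # ITS
    its_genotypes_per_species: int = 3
    species_its_divergence: float = 0.08
    genotype_its_divergence: float = 0.004
    its_length_bounds: tuple[int, int] = (485, 515)
    # sampling
    specimens_per_cell: int = 5
    n_fungal_only_per_cell: int = 1
    n_photobiont_only_per_cell: int = 2
    pool_size: int = 8
    tripartite_pool_size: int = 6
    founder_concentration: float = 0.3
    n_trans_regional: int = 1
    ensure_all_genotypes_sampled: bool = True

    def __post_init__(self) -> None:
        for name in ("branch_slippage_rate", "member_mutation_rate",
                     "member_slippage_rate", "species_its_divergence",
                     "genotype_its_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0, 1], got {v}")
        if self.founder_concentration <= 0:
            raise SynthError("founder_concentration must be positive")
        for name in ("its_genotypes_per_species", "pool_size", "tripartite_pool_size"):
            if getattr(self, name) < 1:
                raise SynthError(f"{name} must be positive")
        if self.specimens_per_cell < 0:
            raise SynthError("specimens_per_cell must be >= 0")
        if not set(self.tripartite_species) <= set(self.species_names):
            raise SynthError("tripartite_species must be a subset of species_names")


@dataclass
class GroundTruth:
    """Everything the generator knows; basis for recovery tests."""

    seed: int
    intron_genotypes: dict[str, dict] = field(default_factory=dict)
    its_genotypes: dict[str, dict] = field(default_factory=dict)
    seq_to_intron_genotype: dict[str, str] = field(default_factory=dict)
    seq_to_its_genotype: dict[str, str] = field(default_factory=dict)
    specimens: list[dict] = field(default_factory=list)
    planted_trans_regional: list[dict] = field(default_factory=list)
    composition: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# intron simulation


@dataclass
class _IntronParts:
    """Mutable component representation of one intron genotype."""

    core5: str
    p5b_loop: str
    spacer: str
    left_units: list[str]
    indel_insertions: list[tuple[int, str]]  # (unit index, element sequence)
    central_loop: str
    core3: str

    def assemble(self, profile: ReferenceProfile) -> str:
        left = []
        ins = dict(self.indel_insertions)
        for i, u in enumerate(self.left_units):
            if i in ins:
                left.append(ins[i])
            left.append(u)
        if len(self.left_units) in ins:
            left.append(ins[len(self.left_units)])
        left_arm = "".join(left)
        p5b = (profile.p5b_flank5 + P5B_ARM + self.p5b_loop
               + iupac.revcomp(P5B_ARM) + profile.p5b_flank3)
        p6b = (profile.p6b_flank5 + left_arm + self.central_loop
               + iupac.revcomp(left_arm) + profile.p6b_flank3)
        return self.core5 + p5b + self.spacer + p6b + self.core3

    def copy(self) -> "_IntronParts":
        return _IntronParts(self.core5, self.p5b_loop, self.spacer,
                            list(self.left_units), list(self.indel_insertions),
                            self.central_loop, self.core3)


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b in "ACGT" else sorted(iupac.IUPAC_SETS[b])[rng.integers(len(iupac.IUPAC_SETS[b]))]
        for b in pattern
    )


def _anchor_ok(seq: str, profile: ReferenceProfile) -> bool:
    return (
        iupac.count_motif(seq, profile.p5b_flank5) == 1
        and iupac.count_motif(seq, profile.p6b_flank5) == 1
        and iupac.find_motif(seq, profile.p5b_flank3) > seq.find(profile.p5b_flank5)
        and iupac.count_motif(seq, FLANK5_MOTIF) == 0
    )


def _mutate_parts(parts: _IntronParts, config: SimulationConfig,
                  profile: ReferenceProfile, rng: np.random.Generator) -> _IntronParts:
    """One branching step: optional whole-unit slippage plus substitutions in
    the mutable zones (cores, spacer, repeat arms)."""
    child = parts.copy()
    if config.branch_slippage_rate > 0 and rng.random() < config.branch_slippage_rate:
        if len(child.left_units) > 2 and rng.random() < 0.5:
            child.left_units.pop()
        else:
            # duplicate the unit adjacent to the loop (tandem slippage)
            child.left_units.append(child.left_units[-1])
    n_mut = rng.poisson(config.branch_substitutions)
    for _ in range(n_mut):
        zone = rng.integers(4)
        if zone == 0:
            child.core5 = _substitute(child.core5, rng)
        elif zone == 1:
            child.spacer = _substitute(child.spacer, rng)
        elif zone == 2:
            child.core3 = _substitute(child.core3, rng)
        else:
            # repeat-arm substitution, kept above the match threshold
            k = int(rng.integers(len(child.left_units)))
            unit = child.left_units[k]
            pattern = (profile.class1_consensus
                       if _unit_class(unit, profile) == CLASS1
                       else profile.class2_consensus)
            if sum(b not in iupac.IUPAC_SETS[p] for b, p in zip(unit, pattern)) >= 2:
                continue
            child.left_units[k] = _substitute(unit, rng)
    return child


def _unit_class(unit: str, profile: ReferenceProfile) -> str:
    s1 = iupac.motif_score(unit, profile.class1_consensus)
    s2 = iupac.motif_score(unit, profile.class2_consensus)
    return CLASS1 if s1 >= s2 else CLASS2


def _substitute(seq: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(seq)))
    old = seq[i]
    new = "ACGT".replace(old, "")[rng.integers(3)]
    return seq[:i] + new + seq[i + 1 :]


def simulate_introns(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    profile: Optional[ReferenceProfile] = None,
) -> tuple[SequenceSet, GroundTruth]:
    """Generate one intron sequence per planted genotype, with ground truth.

    Each subgroup template is instantiated (flank anchors + repeat arms +
    subgroup indel elements + lineage central loop and P5b signature), then
    genotypes are derived by sequential branching.  With both branching
    processes at zero the genotypes of a subgroup collapse to identical
    sequences (degenerate; a warning is raised).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    profile = profile or ReferenceProfile.default()
    lo, hi = config.intron_length_bounds
    truth = GroundTruth(seed=config.seed)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    degenerate = (config.branch_substitutions == 0
                  and config.branch_slippage_rate == 0)
    for spec in config.subgroups:
        unknown = set(spec.indel_tags) - set(profile.indel_elements)
        if unknown:
            raise SynthError(f"subgroup {spec.key}: unknown indel tags {unknown}")
        parent: Optional[_IntronParts] = None
        for g in range(spec.n_genotypes):
            for _attempt in range(_MAX_RETRIES):
                if parent is None:
                    consensus = (profile.class1_consensus
                                 if spec.repeat_class == CLASS1
                                 else profile.class2_consensus)
                    units = [_resolve_iupac(consensus, rng)
                             for _ in range(spec.base_repeats_per_arm)]
                    n_units = len(units)
                    insertions = [
                        (max(1, (i + 1) * n_units // (len(spec.indel_tags) + 1)),
                         profile.indel_elements[t])
                        for i, t in enumerate(spec.indel_tags)
                    ]
                    loop = (CENTRAL_LOOP_BIPARTITE
                            if spec.lineage == BIPARTITE_TYPE
                            else _resolve_iupac(CENTRAL_LOOP_TRIPARTITE, rng))
                    cand = _IntronParts(
                        core5=CORE5,
                        p5b_loop=(P5B_LOOP_BIPARTITE
                                  if spec.lineage == BIPARTITE_TYPE
                                  else P5B_LOOP_TRIPARTITE),
                        spacer=SPACER,
                        left_units=units,
                        indel_insertions=insertions,
                        central_loop=loop,
                        core3=CORE3,
                    )
                else:
                    cand = _mutate_parts(parent, config, profile, rng)
                seq = cand.assemble(profile)
                if len(seq) < 200:
                    raise SynthError(
                        f"subgroup {spec.key}: intron of {len(seq)} bp < 200; "
                        "configuration yields no valid template"
                    )
                if not (lo <= len(seq) <= hi) or not _anchor_ok(seq, profile):
                    continue
                if seq in seen and not degenerate:
                    continue
                break
            else:
                raise SynthError(
                    f"subgroup {spec.key}: could not derive a distinct valid "
                    f"genotype after {_MAX_RETRIES} attempts"
                )
            if seq in seen and degenerate:
                warnings.warn(
                    f"subgroup {spec.key}: zero-variation config, genotype "
                    f"{spec.key}_g{g} is sequence-identical to an earlier one",
                    stacklevel=2,
                )
            seen.add(seq)
            key = f"{spec.key}_g{g}"
            records.append((key, seq))
            truth.intron_genotypes[key] = {
                "subgroup": spec.key,
                "lineage": spec.lineage,
                "repeat_class": spec.repeat_class,
                "indel_tags": list(spec.indel_tags),
                "repeats_per_arm": len(cand.left_units),
                "sequence": seq,
            }
            # next genotype branches off this one
            parent = cand
    return SequenceSet(records=records, molecule="trnL_intron"), truth


# ---------------------------------------------------------------------------
# ITS simulation


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT".replace(out[i], "")[rng.integers(3)]
    return "".join(out)


def _its_clean(its: str) -> bool:
    return (iupac.count_motif(its, FLANK5_MOTIF) == 0
            and all(iupac.count_motif(its, v) == 0 for v in ITS_FLANK3_VARIANTS))


def simulate_its(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SequenceSet, GroundTruth]:
    """Generate ITS amplicons: per-species backbones at the configured
    divergence, within-species genotypes at small divergence, each planted
    ITS wrapped in the conserved rns / rnl flank motifs plus padding."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.its_length_bounds
    truth = GroundTruth(seed=config.seed)
    records: list[tuple[str, str]] = []
    ancestor = _random_seq((lo + hi) // 2, rng)
    backbones: dict[str, str] = {}
    for sp in config.species_names:
        for _ in range(_MAX_RETRIES):
            target = int(rng.integers(lo, hi + 1))
            bb = _diverge(ancestor, config.species_its_divergence, rng)
            if len(bb) > target:
                cut = int(rng.integers(0, len(bb) - target + 1))
                bb = bb[:cut] + bb[cut + len(bb) - target :]
            elif len(bb) < target:
                pos = int(rng.integers(0, len(bb) + 1))
                bb = bb[:pos] + _random_seq(target - len(bb), rng) + bb[pos:]
            if _its_clean(bb) and bb not in backbones.values():
                break
        else:
            raise SynthError(f"could not generate a clean ITS backbone for {sp}")
        backbones[sp] = bb
    collisions = len(backbones) - len(set(backbones.values()))
    if collisions:
        warnings.warn(f"{collisions} species ITS backbones collide "
                      "(species_its_divergence too low or lengths equal)")
    for sp, bb in backbones.items():
        pad5 = _random_seq(int(rng.integers(18, 25)), rng)
        pad3 = _random_seq(int(rng.integers(18, 25)), rng)
        seen_its: set[str] = set()
        for g in range(config.its_genotypes_per_species):
            for _ in range(_MAX_RETRIES):
                its = _diverge(bb, config.genotype_its_divergence, rng)
                flank3 = ITS_FLANK3_VARIANTS[rng.integers(2)]
                if not _its_clean(its):
                    continue
                if its in seen_its and config.genotype_its_divergence > 0:
                    continue
                amplicon = pad5 + FLANK5_MOTIF + its + flank3 + pad3
                if iupac.count_motif(amplicon, FLANK5_MOTIF) == 1:
                    break
            else:
                raise SynthError(f"could not derive distinct ITS genotype for {sp}")
            seen_its.add(its)
            key = f"{sp.replace(' ', '_').replace('.', '')}_its{g}"
            records.append((key, amplicon))
            truth.its_genotypes[key] = {"species": sp, "its": its,
                                        "amplicon": amplicon}
    return SequenceSet(records=records, molecule="ITS"), truth


# ---------------------------------------------------------------------------
# sampling


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    its_set: SequenceSet
    intron_set: SequenceSet
    records: list[SpecimenRecord]
    truth: GroundTruth


def _noisy_copy(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    for _ in range(n):
        seq = _substitute(seq, rng)
    return seq


def simulate_sampling(
    config: SimulationConfig,
    intron_set: SequenceSet,
    intron_truth: GroundTruth,
    its_set: SequenceSet,
    its_truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SpecimenRecord], SequenceSet, SequenceSet, GroundTruth]:
    """Sample specimens with founder-skewed regional genotype frequencies.

    Each species draws a compatible photobiont pool; per region the pool
    frequencies are Dirichlet(concentration x global weights) draws, so a low
    ``founder_concentration`` makes one or few genotypes regionally dominant.
    Emits per-specimen sequence copies, paired or single, plus the requested
    planted trans-regional (fungal genotype, photobiont genotype) pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed)
    truth.intron_genotypes = intron_truth.intron_genotypes
    truth.its_genotypes = its_truth.its_genotypes
    intron_seq = dict(intron_set.records)
    its_seq = dict(its_set.records)
    bi_keys = [k for k, v in intron_truth.intron_genotypes.items()
               if v["lineage"] == BIPARTITE_TYPE]
    tri_keys = [k for k, v in intron_truth.intron_genotypes.items()
                if v["lineage"] == TRIPARTITE_TYPE]
    its_by_species: dict[str, list[str]] = {}
    for k, v in its_truth.its_genotypes.items():
        its_by_species.setdefault(v["species"], []).append(k)

    pools: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    for sp in config.species_names:
        if sp in config.tripartite_species:
            source, size = tri_keys, config.tripartite_pool_size
        else:
            source, size = bi_keys, config.pool_size
        size = min(size, len(source))
        if size < 1:
            raise SynthError(f"no compatible genotypes available for {sp}")
        pools[sp] = sorted(str(k) for k in rng.choice(source, size=size, replace=False))
        weights[sp] = rng.dirichlet(np.ones(size))

    records: list[SpecimenRecord] = []
    its_records: list[tuple[str, str]] = []
    intron_records: list[tuple[str, str]] = []
    counter = 0

    def _emit(species: str, region: str, with_fungal: bool, with_photo: bool,
              its_key: Optional[str] = None, intron_key: Optional[str] = None):
        nonlocal counter
        counter += 1
        spec_id = f"s{counter:04d}"
        f_id = p_id = None
        if with_fungal:
            its_key = its_key or its_by_species[species][
                rng.integers(len(its_by_species[species]))
            ]
            f_id = f"{spec_id}_ITS"
            its_records.append(
                (f_id, _noisy_copy(its_seq[its_key], config.member_mutation_rate, rng))
            )
            truth.seq_to_its_genotype[f_id] = its_key
        if with_photo:
            assert intron_key is not None
            p_id = f"{spec_id}_trnL"
            intron_records.append(
                (p_id, _noisy_copy(intron_seq[intron_key],
                                   config.member_mutation_rate, rng))
            )
            truth.seq_to_intron_genotype[p_id] = intron_key
        records.append(SpecimenRecord(
            specimen_id=spec_id, fungal_species=species, fungal_seq_id=f_id,
            photobiont_seq_id=p_id, region=region, locality=None,
        ))
        truth.specimens.append({
            "specimen_id": spec_id, "species": species, "region": region,
            "its_genotype": its_key if with_fungal else None,
            "intron_genotype": intron_key if with_photo else None,
        })
        return spec_id

    for sp in config.species_names:
        pool, w_global = pools[sp], weights[sp]
        for region in config.regions:
            alpha = config.founder_concentration * len(pool) * w_global
            w_region = rng.dirichlet(np.maximum(alpha, 1e-3))
            for _ in range(config.specimens_per_cell):
                gk = pool[int(rng.choice(len(pool), p=w_region))]
                _emit(sp, region, True, True, intron_key=gk)
            for _ in range(config.n_fungal_only_per_cell):
                _emit(sp, region, True, False)
            for _ in range(config.n_photobiont_only_per_cell):
                gk = pool[int(rng.choice(len(pool), p=w_region))]
                _emit(sp, region, False, True, intron_key=gk)

    # planted trans-regional combinations
    bi_species = [s for s in config.species_names
                  if s not in config.tripartite_species]
    for t in range(config.n_trans_regional):
        sp = bi_species[t % len(bi_species)]
        its_key = its_by_species[sp][0]
        intron_key = pools[sp][0]
        r1, r2 = config.regions[0], config.regions[min(1, len(config.regions) - 1)]
        for region in (r1, r2):
            _emit(sp, region, True, True, its_key=its_key, intron_key=intron_key)
        truth.planted_trans_regional.append({
            "species": sp, "its_genotype": its_key,
            "intron_genotype": intron_key, "regions": [r1, r2],
        })

    if config.ensure_all_genotypes_sampled:
        sampled = set(truth.seq_to_intron_genotype.values())
        for i, gk in enumerate(k for k in intron_truth.intron_genotypes
                               if k not in sampled):
            lineage = intron_truth.intron_genotypes[gk]["lineage"]
            same_lineage = [
                s for s in config.species_names
                if (s in config.tripartite_species) == (lineage == TRIPARTITE_TYPE)
            ]
            hosts = [s for s, p in pools.items() if gk in p] or same_lineage \
                or list(config.species_names)
            _emit(hosts[0], config.regions[i % len(config.regions)],
                  False, True, intron_key=gk)
        sampled_its = set(truth.seq_to_its_genotype.values())
        for i, ik in enumerate(k for k in its_truth.its_genotypes
                               if k not in sampled_its):
            sp = its_truth.its_genotypes[ik]["species"]
            _emit(sp, config.regions[i % len(config.regions)],
                  True, False, its_key=ik)

    truth.composition = {
        "n_paired": sum(1 for r in records if r.is_paired),
        "n_fungal_only": sum(1 for r in records
                             if r.fungal_seq_id and not r.photobiont_seq_id),
        "n_photobiont_only": sum(1 for r in records
                                 if r.photobiont_seq_id and not r.fungal_seq_id),
    }
    return (
        records,
        SequenceSet(records=its_records, molecule="ITS"),
        SequenceSet(records=intron_records, molecule="trnL_intron"),
        truth,
    )


def simulate_dataset(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """End-to-end simulation: genotypes, ITS genotypes, specimen sampling."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genotype_set, intron_truth = simulate_introns(config, rng)
    its_geno_set, its_truth = simulate_its(config, rng)
    records, its_set, intron_set, truth = simulate_sampling(
        config, genotype_set, intron_truth, its_geno_set, its_truth, rng
    )
    return SimulatedDataset(
        config=config, its_set=its_set, intron_set=intron_set,
        records=records, truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write introns.fa, its.fa, metadata.tsv and truth.json."""
    from .seq_io import write_fasta, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.intron_set, outdir / "introns.fa")
    write_fasta(ds.its_set, outdir / "its.fa")
    write_metadata(ds.records, outdir / "metadata.tsv")
    ds.truth.to_json(outdir / "truth.json")
    (outdir / "seed.txt").write_text(f"seed={ds.config.seed}\n")
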