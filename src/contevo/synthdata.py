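"""Synthetic two-phase evolution datasets.

Generates per-population mutation tables and competition-assay colony counts
with the statistical structure the downstream analysis assumes, so every
pipeline stage runs and can be calibrated without any external data.

The default configuration emulates the study conditions of a two-phase
*E. coli* thermal-stress experiment: ten founders (five per adaptive
pathway, *rho* and *rpoB*) plus an ancestor control group, six replicate
populations per founder and twelve controls with the observed extinction
pattern (65 surviving populations); ~21 mutations per population at >=5%
frequency drawn from pathway-specific gene modules and a shared background
pool; a frequency mixture with 45% of mutations below 10% and ~8.5% fixed
(>85%); and competition colony counts Poisson-sampled around the expected
plating depth under per-founder true relative fitness values taken from the
study's printed fitness tables.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict

import numpy as np

from .fitness import CompetitionAssay
from .mutations import GroupLabeling, MutationRecord

GENOME_LENGTH = 4_629_812  # E. coli B REL606 scale, coordinates only

#: Phase-2 founders: (founder_id, pathway, founder fitness vs the grand
#: ancestor at the cold temperature) — the founder fitness column is used as
#: the ANCOVA covariate and slope-regression x-axis.
STUDY_FOUNDERS: list[tuple[str, str, float]] = [
    ("rho_T231A", "rho", 0.970),
    ("rho_V206A", "rho", 1.004),
    ("rho_I15N_1", "rho", 0.952),
    ("rho_I15N_2", "rho", 1.015),
    ("rho_A43T", "rho", 1.008),
    ("rpoB_I966S", "rpoB", 0.895),
    ("rpoB_G556S", "rpoB", 0.962),
    ("rpoB_E84G", "rpoB", 1.031),
    ("rpoB_I966N", "rpoB", 0.982),
    ("rpoB_I572L", "rpoB", 0.899),
]

#: True relative fitness per founder and competition setting:
#: vs_ancestor_cold — evolved population vs grand ancestor at 19 C;
#: vs_founder_cold — evolved population vs its own founder at 19 C;
#: vs_founder_hot  — evolved population vs its own founder at 42 C
#: (trade-off axis).  Values follow the study's printed per-founder means.
STUDY_TRUE_FITNESS: dict[str, dict[str, float]] = {
    "rho_T231A": {"vs_ancestor_cold": 1.02, "vs_founder_cold": 1.12, "vs_founder_hot": 0.91},
    "rho_V206A": {"vs_ancestor_cold": 1.09, "vs_founder_cold": 1.06, "vs_founder_hot": 0.80},
    "rho_I15N_1": {"vs_ancestor_cold": 1.00, "vs_founder_cold": 1.04, "vs_founder_hot": 0.93},
    "rho_I15N_2": {"vs_ancestor_cold": 1.11, "vs_founder_cold": 1.13, "vs_founder_hot": 0.98},
    "rho_A43T": {"vs_ancestor_cold": 1.07, "vs_founder_cold": 1.01, "vs_founder_hot": 0.96},
    "rpoB_I966S": {"vs_ancestor_cold": 1.08, "vs_founder_cold": 1.15, "vs_founder_hot": 1.04},
    "rpoB_G556S": {"vs_ancestor_cold": 1.00, "vs_founder_cold": 1.08, "vs_founder_hot": 0.52},
    "rpoB_E84G": {"vs_ancestor_cold": 1.02, "vs_founder_cold": 1.08, "vs_founder_hot": 1.00},
    "rpoB_I966N": {"vs_ancestor_cold": 1.01, "vs_founder_cold": 1.14, "vs_founder_hot": 0.92},
    "rpoB_I572L": {"vs_ancestor_cold": 0.96, "vs_founder_cold": 1.06, "vs_founder_hot": 0.90},
    "ancestor": {"vs_ancestor_cold": 1.04, "vs_founder_cold": 1.04, "vs_founder_hot": 1.00},
}

#: observed per-founder extinction pattern (populations lost before the end
#: of the experiment); 72 started -> 65 survived
STUDY_EXTINCTIONS: dict[str, int] = {
    "rpoB_I966S": 4,
    "rpoB_I572L": 2,
    "ancestor": 1,
}


@dataclass(frozen=True)
class FreqMixture:
    """Three-component mixture for mutation frequencies: low (<0.10), mid,
    and fixed (>0.85).  Each component is a Beta(a, b) rescaled into its
    interval; interval edges respect the segregating (>=5%, inclusive) and
    fixed (>85%, exclusive) conventions."""

    weights: tuple[float, float, float] = (0.45, 0.465, 0.085)
    low: tuple[float, float] = (1.0, 1.0)
    mid: tuple[float, float] = (1.2, 3.0)
    fixed: tuple[float, float] = (2.0, 1.0)

    def validate(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.choice(3, size=size, p=self.weights)
        out = np.empty(size)
        for i, (a, b), (lo, hi) in zip(
            range(3),
            (self.low, self.mid, self.fixed),
            ((0.05, 0.0999), (0.10, 0.85), (0.8501, 1.0)),
        ):
            mask = comp == i
            out[mask] = lo + (hi - lo) * rng.beta(a, b, size=int(mask.sum()))
        return out


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_pathways: int = 2
    founders_per_pathway: int = 5
    replicates_per_founder: int = 6
    n_control_replicates: int = 12
    module_pool_size: int = 12
    background_pool_size: int = 40
    module_hit_prob: float = 0.15
    mutations_per_pop_mean: float = 21.0
    freq_mixture: FreqMixture = field(default_factory=FreqMixture)
    true_fitness_map: Mapping[str, Mapping[str, float]] | None = None
    doublings_reference: float = float(np.log2(100.0))
    plating_depth: float = 500.0
    assay_replicates: int = 3
    population_fitness_sd: float = 0.02
    extinctions: Mapping[str, int] | None = None
    founder_private_mutations: int = 2
    intergenic_fraction: float = 0.55
    pseudogene_fraction: float = 0.05
    large_deletion_prob: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.n_pathways < 1 or self.founders_per_pathway < 1:
            raise ValueError("need >=1 pathway and founder per pathway")
        if self.module_pool_size < 1 or self.background_pool_size < 1:
            raise ValueError("pool sizes must be >= 1")
        if not (0.0 <= self.module_hit_prob <= 1.0):
            raise ValueError("module_hit_prob must lie in [0, 1]")
        if self.mutations_per_pop_mean <= 0:
            raise ValueError("mutations_per_pop_mean must be > 0")
        if self.doublings_reference <= 0:
            raise ValueError("doublings_reference must be > 0")
        self.freq_mixture.validate()

    def is_study_shape(self) -> bool:
        return self.n_pathways == 2 and self.founders_per_pathway == 5

    def founders(self) -> list[tuple[str, str, float]]:
        """(founder_id, pathway, founder fitness) triples."""
        if self.is_study_shape():
            return list(STUDY_FOUNDERS)
        out = []
        for p in range(self.n_pathways):
            pw = ("rho", "rpoB")[p] if self.n_pathways <= 2 else f"pw{p + 1}"
            for f in range(self.founders_per_pathway):
                out.append((f"{pw}_F{f + 1}", pw, 1.0))
        return out

    def fitness_map(self) -> dict[str, dict[str, float]]:
        if self.true_fitness_map is not None:
            return {k: dict(v) for k, v in self.true_fitness_map.items()}
        if self.is_study_shape():
            return {k: dict(v) for k, v in STUDY_TRUE_FITNESS.items()}
        default = {"vs_ancestor_cold": 1.04, "vs_founder_cold": 1.08,
                   "vs_founder_hot": 0.89}
        out = {fid: dict(default) for fid, _, _ in self.founders()}
        out["ancestor"] = dict(default)
        return out

    def extinction_map(self) -> dict[str, int]:
        if self.extinctions is not None:
            return dict(self.extinctions)
        if self.is_study_shape() and self.replicates_per_founder == 6 \
                and self.n_control_replicates == 12:
            return dict(STUDY_EXTINCTIONS)
        return {}


@dataclass(frozen=True)
class SyntheticDataset:
    mutation_table: list[MutationRecord]
    labeling: GroupLabeling
    assays: list[CompetitionAssay]
    truth: dict

    @property
    def founder_genotypes(self) -> dict[str, list[str]]:
        return self.truth["founder_genotypes"]


def _make_region_ids(
    rng: np.random.Generator,
    count: int,
    prefix: str,
    intergenic_fraction: float,
    pseudogene_fraction: float,
    start: int,
) -> list[tuple[str, str]]:
    """(region_id, region_kind) pairs with gene/intergenic/pseudogene naming."""
    out = []
    i = start
    for _ in range(count):
        u = rng.random()
        if u < intergenic_fraction:
            out.append((f"{prefix}{i:03d}/{prefix}{i + 1:03d}", "intergenic"))
            i += 2
        elif u < intergenic_fraction + pseudogene_fraction:
            out.append((f"{prefix}{i:03d}_pseudo", "pseudogene"))
            i += 1
        else:
            out.append((f"{prefix}{i:03d}", "genic"))
            i += 1
    return out


# conditional effect/type frequencies given region kind; within genes most
# point mutations are nonsynonymous, intergenic calls are almost all points
_GENIC_EFFECTS = (("nonsynonymous", "point", 0.673),
                  ("synonymous", "point", 0.077),
                  ("frameshift", "indel", 0.25))


def _draw_effect(rng: np.random.Generator, kind: str,
                 large_deletion_prob: float) -> tuple[str, str]:
    if rng.random() < large_deletion_prob:
        return "large_deletion", "large_deletion"
    if kind == "intergenic":
        return "intergenic", "point" if rng.random() < 0.958 else "indel"
    if kind == "pseudogene":
        return "pseudogene", "point" if rng.random() < 0.8 else "indel"
    effects, types, probs = zip(*_GENIC_EFFECTS)
    i = rng.choice(len(effects), p=np.asarray(probs) / sum(probs))
    return effects[i], types[i]


def simulate_competition(
    true_w: float,
    doublings_reference: float,
    plating_depth: float,
    n_assays: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    population_id: str = "pop",
    competitor_id: str = "reference",
    environment: str = "cold",
) -> list[CompetitionAssay]:
    """Simulate competition assays under a true relative fitness.

    Over one competition cycle the reference grows 2**D-fold (D doublings)
    and the evolved line 2**(w*D)-fold.  Both competitors start 1:1 with an
    expected ``plating_depth / 2`` colonies each on the initial plate; the
    final culture is plated at a further 2**-D dilution, so expected final
    reference colonies match the initial plate while the evolved line's
    expectation scales with 2**((w-1)*D).  Observed colony counts are
    Poisson; densities are counts times the exact dilution factor.  Assays
    where any plate yields zero colonies are flagged ``failed`` rather than
    emitting zero counts.
    """
    if true_w <= 0:
        raise ValueError("true_w must be > 0")
    if doublings_reference <= 0:
        raise ValueError("doublings_reference must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    half = plating_depth / 2.0
    final_dilution = 2.0 ** doublings_reference  # density = count * dilution
    exp_final_evolved = half * 2.0 ** ((true_w - 1.0) * doublings_reference)
    out = []
    for rep in range(n_assays):
        c_ie, c_ia = rng.poisson(half), rng.poisson(half)
        c_fe = rng.poisson(exp_final_evolved)
        c_fa = rng.poisson(half)
        failed = min(c_ie, c_ia, c_fe, c_fa) == 0
        out.append(
            CompetitionAssay(
                population_id=population_id,
                competitor_id=competitor_id,
                environment=environment,
                replicate=rep,
                n_i_evolved=max(c_ie, 1) if failed else c_ie,
                n_f_evolved=(max(c_fe, 1) if failed else c_fe) * final_dilution,
                n_i_reference=max(c_ia, 1) if failed else c_ia,
                n_f_reference=(max(c_fa, 1) if failed else c_fa) * final_dilution,
                failed=failed,
            )
        )
    return out


def simulate_mutation_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset (mutation table, labeling, assays).

    Per population the number of Phase-2 mutations is Poisson with mean
    ``mutations_per_pop_mean``; each mutation's region comes from the
    founder's pathway module with probability ``module_hit_prob``, otherwise
    from the shared background pool; its frequency is drawn from the
    configured mixture.  Founder-defining mutations are injected at
    frequency 1.0 into every descendant population.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    founders = config.founders()
    pathways = sorted({pw for _, pw, _ in founders})

    # region pools: one module per pathway + shared background, all disjoint
    pools: dict[str, list[tuple[str, str]]] = {}
    start = 1
    for pw in pathways:
        pools[pw] = _make_region_ids(
            rng, config.module_pool_size, f"{pw[:2]}m",
            config.intergenic_fraction, config.pseudogene_fraction, start,
        )
        start += 2 * config.module_pool_size + 10
    background = _make_region_ids(
        rng, config.background_pool_size, "bg",
        config.intergenic_fraction, config.pseudogene_fraction, 1,
    )
    all_ids = [r for pool in pools.values() for r, _ in pool] + [
        r for r, _ in background
    ]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("region ids must be unique across module and "
                         "background pools")

    # founder-defining mutations: the pathway gene + private regions
    founder_genotypes: dict[str, list[str]] = {}
    for fid, pw, _ in founders:
        regions = [pw] + [
            f"{fid}_p{j + 1}" for j in range(config.founder_private_mutations)
        ]
        founder_genotypes[fid] = regions
    founder_genotypes["ancestor"] = []

    # population roster with extinctions removed
    extinct = config.extinction_map()
    roster: list[tuple[str, str, str]] = []  # (population, founder, pathway)
    for fid, pw, _ in founders:
        n = config.replicates_per_founder - extinct.get(fid, 0)
        for r in range(n):
            roster.append((f"{fid}_r{r + 1}", fid, pw))
    n_ctl = config.n_control_replicates - extinct.get("ancestor", 0)
    for r in range(n_ctl):
        roster.append((f"ancestor_r{r + 1}", "ancestor", "ancestor"))

    region_positions = {
        rid: int(rng.integers(1, GENOME_LENGTH + 1))
        for rid in all_ids + [r for regs in founder_genotypes.values() for r in regs]
    }
    region_kind = {rid: kind for pool in pools.values() for rid, kind in pool}
    region_kind.update({rid: kind for rid, kind in background})

    records: list[MutationRecord] = []
    for pop, fid, pw in roster:
        # inherited founder mutations, fixed by construction
        for rid in founder_genotypes[fid]:
            records.append(
                MutationRecord(
                    population_id=pop, founder_id=fid, pathway=pw,
                    region_id=rid, region_kind="genic", mutation_type="point",
                    effect="nonsynonymous", position=region_positions[rid],
                    frequency=1.0, origin="phase1_founder",
                )
            )
        n_mut = rng.poisson(config.mutations_per_pop_mean)
        freqs = config.freq_mixture.sample(rng, n_mut)
        module = pools.get(pw, [])
        for m in range(n_mut):
            use_module = module and rng.random() < config.module_hit_prob
            pool = module if use_module else background
            rid, kind = pool[rng.integers(len(pool))]
            effect, mtype = _draw_effect(rng, kind, config.large_deletion_prob)
            records.append(
                MutationRecord(
                    population_id=pop, founder_id=fid, pathway=pw,
                    region_id=rid, region_kind=kind, mutation_type=mtype,
                    effect=effect, position=region_positions[rid],
                    frequency=float(freqs[m]), origin="phase2",
                )
            )

    labeling = GroupLabeling(
        mapping={pop: (pw, fid) for pop, fid, pw in roster}
    )

    # competition assays under the per-founder true fitness values, with a
    # small per-population deviation (replicate populations differ)
    fmap = config.fitness_map()
    assays: list[CompetitionAssay] = []
    true_pop_w: dict[tuple[str, str], float] = {}
    for pop, fid, pw in roster:
        for setting, base_w in fmap[fid].items():
            w = max(base_w + rng.normal(0.0, config.population_fitness_sd), 0.05)
            true_pop_w[(pop, setting)] = w
            competitor = "ancestor" if setting == "vs_ancestor_cold" else fid
            assays.extend(
                simulate_competition(
                    true_w=w,
                    doublings_reference=config.doublings_reference,
                    plating_depth=config.plating_depth,
                    n_assays=config.assay_replicates,
                    rng=rng,
                    population_id=pop,
                    competitor_id=competitor,
                    environment=setting,
                )
            )

    truth = {
        "config": _config_dict(config),
        "module_pools": {pw: [r for r, _ in pool] for pw, pool in pools.items()},
        "background_pool": [r for r, _ in background],
        "founder_genotypes": founder_genotypes,
        "true_fitness": fmap,
        "true_population_fitness": {
            f"{pop}|{setting}": w for (pop, setting), w in true_pop_w.items()
        },
    }
    return SyntheticDataset(
        mutation_table=records, labeling=labeling, assays=assays, truth=truth
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["true_fitness_map"] = (
        None if config.true_fitness_map is None
        else {k: dict(v) for k, v in config.true_fitness_map.items()}
    )
    d["extinctions"] = None if config.extinctions is None else dict(config.extinctions)
    return d


def write_dataset(dataset: SyntheticDataset, mutation_tsv, assay_csv,
                  truth_json) -> None:
    from .fitness import write_assay_csv
    from .mutations import write_mutation_table

    write_mutation_table(dataset.mutation_table, mutation_tsv)
    write_assay_csv(dataset.assays, assay_csv)
    with open(truth_json, "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
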