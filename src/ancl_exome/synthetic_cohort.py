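"""Gene-dropping simulator for pedigree-structured exome cohorts.

The generator emulates the statistical structure of the study family:

* every founder carries a private pool of novel (database-absent) functional
  variants, so that each pedigree member carries about 674 novel
  nonsynonymous calls -- the study's observed per-exome mean;
* common variants segregate in the population with a database frequency
  spectrum (a common/rare mixture), are assigned to founders under
  Hardy-Weinberg proportions, and carry their frequency in ``db_flags``;
* founder alleles are dropped through the pedigree by Mendelian gene
  dropping: each parental allele is transmitted with probability 1/2, so a
  rare variant carried by one individual is carried by a relative with
  probability ``2 * kinship`` (0.5 for siblings, 0.125 for first cousins);
* samples sequenced on one flow cell share a set of systematic artifact
  calls (novel, identical across those samples), the failure mode that
  inflates the affected-pair intersection before control subtraction;
* one heterozygous causal variant (novel, missense) is implanted in every
  affected individual and in no unaffected individual.

Variants are exchangeable points: there is no linkage map, so sharing is
per-variant Bernoulli -- the genome-average arithmetic the study design uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cascade as _cascade
from .cascade import CascadeConfig, FilterTrace, run_cascade
from .segregation import GenotypePanel
from .variant_io import (
    Individual,
    Pedigree,
    SampleExome,
    VariantCall,
    VariantKey,
)

FUNCTIONAL_CLASS_WEIGHTS = {"missense": 0.95, "nonsense": 0.01, "splice": 0.04}
NONFUNCTIONAL_CLASS_WEIGHTS = {"synonymous": 0.45, "intronic": 0.45, "intergenic": 0.10}


def study_pedigree() -> Pedigree:
    """A three-generation dominant pedigree mirroring the study design.

    The two sequenced affecteds (``aff_c1``, ``aff_c2``) are first cousins
    (expected rare-variant sharing 1/8) and the sequenced control is an
    unaffected sibling of one of them (sharing 1/2 with that affected, 1/8
    with the other).
    """
    return Pedigree(
        [
            Individual("gp1", "male", None, None, "affected"),
            Individual("gp2", "female", None, None, "unaffected"),
            Individual("p1", "male", "gp1", "gp2", "affected"),
            Individual("p2", "female", "gp1", "gp2", "affected"),
            Individual("s1", "female", None, None, "unaffected"),
            Individual("s2", "male", None, None, "unaffected"),
            Individual("aff_c1", "male", "p1", "s1", "affected"),
            Individual("ctrl_sib", "female", "p1", "s1", "unaffected"),
            Individual("aff_c2", "female", "s2", "p2", "affected"),
        ]
    )


@dataclass
class SimConfig:
    """Study-condition parameters of the cohort generator.

    Defaults are the study's own figures: 674 novel nonsynonymous variants
    per exome, 38,179 total coding substitutions (carried as the attrition
    denominator), all three sequenced samples on one flow cell.
    """

    seed: int
    n_background_novel_per_sample: int = 674
    n_total_coding: int = 38_179
    n_db_variants: int = 2_000
    db_common_fraction: float = 0.7
    db_common_freq_range: tuple[float, float] = (0.05, 0.5)
    db_rare_freq_range: tuple[float, float] = (0.0005, 0.005)
    novel_pop_freq_range: tuple[float, float] = (0.0005, 0.005)
    n_population_controls: int = 1_600
    artifact_rate: float = 0.02
    pedigree: Pedigree = field(default_factory=study_pedigree)
    sequenced: tuple[str, ...] = ("aff_c1", "aff_c2", "ctrl_sib")
    flow_cell_groups: tuple[tuple[str, ...], ...] = (("aff_c1", "aff_c2", "ctrl_sib"),)
    causal_chrom: str = "20"
    causal_pos: int = 62_562_226
    depth_mean: float = 124.0
    qual_mean: float = 228.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for rate in (self.artifact_rate, self.db_common_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.n_background_novel_per_sample <= 0 or self.n_total_coding <= 0:
            raise ValueError("variant counts must be positive")
        if len(self.pedigree.affected()) < 2:
            raise ValueError("pedigree must contain at least two affecteds")


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort.

    ``pop_frequency`` is the true population frequency of each variant:
    database-absent ("private") background variants are rare population
    variants rather than family-private ones, which is what makes a large
    control screen informative; artifacts and the causal variant have
    frequency zero.
    """

    causal_key: VariantKey
    carriers: dict[str, bool]
    origin: dict[VariantKey, str]  # private | artifact | db-common | causal
    pop_frequency: dict[VariantKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ped_affected = [s for s, carrier in self.carriers.items() if carrier]
        if not ped_affected:
            raise ValueError("causal variant has no carriers")


def expected_sharing(pedigree: Pedigree, id_a: str, id_b: str) -> float:
    """Probability that a rare variant carried (het) by A is carried by B.

    For a rare allele this is twice the kinship coefficient (capped at 1, so
    the self-sharing fraction is exactly 1).
    """
    return min(1.0, 2.0 * pedigree.kinship(id_a, id_b))


def _gene_drop(
    rng: np.random.Generator, pedigree: Pedigree, founder_counts: dict[str, np.ndarray], n_loci: int
) -> dict[str, np.ndarray]:
    """Drop founder allele counts (0/1/2 per locus) down the pedigree."""
    counts: dict[str, np.ndarray] = {}
    for iid in pedigree.topological_order():
        m = pedigree[iid]
        if m.father is None and m.mother is None:
            counts[iid] = founder_counts.get(iid, np.zeros(n_loci, dtype=np.int8))
            continue
        geno = np.zeros(n_loci, dtype=np.int8)
        for parent in (m.father, m.mother):
            pc = counts[parent]
            # transmit one of two parental alleles: P(alt) = parent count / 2
            geno += (rng.random(n_loci) < pc / 2.0).astype(np.int8)
        counts[iid] = geno
    return counts


def _draw_classes(rng: np.random.Generator, n: int, weights: dict[str, float]) -> np.ndarray:
    names = list(weights)
    p = np.array([weights[k] for k in names])
    return rng.choice(names, size=n, p=p / p.sum())


def _depth_qual(rng: np.random.Generator, n: int, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(cfg.depth_mean, size=n).astype(int)
    qual = np.round(rng.gamma(shape=4.0, scale=cfg.qual_mean / 4.0, size=n), 1)
    return depth, qual


def _count_to_gt(count: int) -> str:
    return {0: "ref/ref", 1: "ref/alt", 2: "alt/alt"}[int(count)]


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[list[SampleExome], GenotypePanel, TruthSet]:
    """Simulate one pedigree cohort; returns (sequenced exomes, genotypes, truth).

    The genotype panel covers *all* pedigree members at the causal locus and
    at every locus carried by any sequenced sample, so extended segregation
    analysis can genotype unsequenced relatives.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = cfg.pedigree
    members = ped.topological_order()
    founders = ped.founders()

    # --- founder-private novel variant pools -------------------------------
    n_novel = cfg.n_background_novel_per_sample
    novel_loci: list[VariantKey] = []
    founder_of: list[str] = []
    for f in founders:
        for j in range(n_novel):
            novel_loci.append(("bg", len(novel_loci) + 1, "A", "G"))
            founder_of.append(f)
    n_bg = len(novel_loci)
    founder_counts = {
        f: (np.array(founder_of) == f).astype(np.int8) for f in founders
    }
    bg_counts = _gene_drop(rng, ped, founder_counts, n_bg)
    bg_classes = _draw_classes(rng, n_bg, FUNCTIONAL_CLASS_WEIGHTS)
    bg_pop_freqs = rng.uniform(*cfg.novel_pop_freq_range, size=n_bg)

    # --- database-common variants ------------------------------------------
    n_db = cfg.n_db_variants
    is_common = rng.random(n_db) < cfg.db_common_fraction
    freqs = np.where(
        is_common,
        rng.uniform(*cfg.db_common_freq_range, size=n_db),
        rng.uniform(*cfg.db_rare_freq_range, size=n_db),
    )
    db_loci: list[VariantKey] = [("db", i + 1, "C", "T") for i in range(n_db)]
    db_founder_counts = {
        f: rng.binomial(2, freqs).astype(np.int8) for f in founders
    }
    db_counts = _gene_drop(rng, ped, db_founder_counts, n_db)
    db_classes = _draw_classes(
        rng,
        n_db,
        {**{k: 0.5 * v for k, v in FUNCTIONAL_CLASS_WEIGHTS.items()},
         **{k: 0.5 * v / sum(NONFUNCTIONAL_CLASS_WEIGHTS.values())
            for k, v in NONFUNCTIONAL_CLASS_WEIGHTS.items()}},
    )

    # --- shared flow-cell artifacts ----------------------------------------
    n_art = int(round(cfg.artifact_rate * n_novel))
    artifact_loci: list[VariantKey] = [("art", i + 1, "G", "T") for i in range(n_art)]
    artifact_classes = _draw_classes(rng, n_art, FUNCTIONAL_CLASS_WEIGHTS) if n_art else np.array([])

    # --- causal variant ------------------------------------------------------
    causal_key: VariantKey = (cfg.causal_chrom, cfg.causal_pos, "T", "G")
    affecteds = set(ped.affected())

    origin: dict[VariantKey, str] = {}
    pop_freq: dict[VariantKey, float] = {}
    for i, key in enumerate(novel_loci):
        origin[key] = "private"
        pop_freq[key] = float(bg_pop_freqs[i])
    for i, key in enumerate(db_loci):
        origin[key] = "db-common"
        pop_freq[key] = float(freqs[i])
    for key in artifact_loci:
        origin[key] = "artifact"
        pop_freq[key] = 0.0
    origin[causal_key] = "causal"
    pop_freq[causal_key] = 0.0

    exomes: list[SampleExome] = []
    panel = GenotypePanel()
    flow_cell_of: dict[str, int] = {}
    for g, group in enumerate(cfg.flow_cell_groups):
        for s in group:
            flow_cell_of[s] = g

    for sid in cfg.sequenced:
        status = ped[sid].status
        calls: list[VariantCall] = []
        bg_c = bg_counts[sid]
        idx = np.nonzero(bg_c)[0]
        depth, qual = _depth_qual(rng, len(idx), cfg)
        for j, i in enumerate(idx):
            calls.append(
                VariantCall(
                    *novel_loci[i],
                    zygosity="hom" if bg_c[i] == 2 else "het",
                    depth=int(depth[j]),
                    qual=float(qual[j]),
                    var_class=str(bg_classes[i]),
                )
            )
        db_c = db_counts[sid]
        idx = np.nonzero(db_c)[0]
        depth, qual = _depth_qual(rng, len(idx), cfg)
        for j, i in enumerate(idx):
            calls.append(
                VariantCall(
                    *db_loci[i],
                    zygosity="hom" if db_c[i] == 2 else "het",
                    depth=int(depth[j]),
                    qual=float(qual[j]),
                    var_class=str(db_classes[i]),
                    db_flags={"dbSNP": float(freqs[i])},
                )
            )
        if sid in flow_cell_of and n_art:
            depth, qual = _depth_qual(rng, n_art, cfg)
            for j, key in enumerate(artifact_loci):
                calls.append(
                    VariantCall(
                        *key,
                        zygosity="het",
                        depth=int(depth[j]),
                        qual=float(qual[j]),
                        var_class=str(artifact_classes[j]),
                    )
                )
        if sid in affecteds:
            depth, qual = _depth_qual(rng, 1, cfg)
            calls.append(
                VariantCall(
                    *causal_key,
                    zygosity="het",
                    depth=int(depth[0]),
                    qual=float(qual[0]),
                    var_class="missense",
                    gene="DNAJC5",
                    prediction="possibly_damaging",
                )
            )
        exomes.append(SampleExome(sid, status, calls))

    # --- genotype panel over all pedigree members ---------------------------
    sequenced_keys: set[VariantKey] = set()
    for ex in exomes:
        sequenced_keys |= ex.key_set()
    for member in members:
        for i, key in enumerate(novel_loci):
            if key in sequenced_keys:
                panel.set(member, key, _count_to_gt(bg_counts[member][i]))
        for i, key in enumerate(db_loci):
            if key in sequenced_keys:
                panel.set(member, key, _count_to_gt(db_counts[member][i]))
        for key in artifact_loci:
            # artifacts are sequencing-batch phantoms: genotyping assays type
            # them as reference in everyone
            panel.set(member, key, "ref/ref")
        panel.set(member, causal_key, "ref/alt" if member in affecteds else "ref/ref")

    truth = TruthSet(
        causal_key=causal_key,
        carriers={m: m in affecteds for m in members},
        origin=origin,
        pop_frequency=pop_freq,
    )
    return exomes, panel, truth


def simulate_control_screen(
    freqs: "dict[VariantKey, float]",
    n_controls: int,
    rng: np.random.Generator,
) -> "dict[VariantKey, ControlScreenResult]":
    """Genotype variants in a simulated population-control cohort.

    Carrier counts are drawn under Hardy-Weinberg proportions at each
    variant's true population frequency; a variant absent from the population
    (frequency 0, e.g. the implanted causal variant) never has carriers, so
    P(zero carriers among 2n chromosomes) = (1 - f)^(2n) for the rest.
    """
    from .segregation import ControlScreenResult

    out: dict[VariantKey, ControlScreenResult] = {}
    for key, f in freqs.items():
        het = int(rng.binomial(n_controls, 2.0 * f * (1.0 - f)))
        hom = int(rng.binomial(n_controls - het, f * f)) if f > 0 else 0
        out[key] = ControlScreenResult(
            key=key, n_controls=n_controls, het_carriers=het, hom_carriers=hom
        )
    return out


def observed_sharing(a: SampleExome, b: SampleExome) -> float:
    """Fraction of A's variant keys that are also carried by B."""
    keys_a = a.key_set()
    if not keys_a:
        return float("nan")
    return len(keys_a & b.key_set()) / len(keys_a)


def db_from_simulation(exomes: Sequence[SampleExome]) -> dict[VariantKey, float]:
    """Database lookup (key -> frequency) from the simulated db annotations."""
    db: dict[VariantKey, float] = {}
    for ex in exomes:
        for call in ex.calls:
            freq = call.max_db_freq()
            if freq is not None:
                db[call.key] = freq
    return db


def attrition_experiment(
    cfg: SimConfig,
    n_reps: int,
    cascade_cfg: Optional[CascadeConfig] = None,
) -> "pd.DataFrame":
    """Simulate + run the cascade ``n_reps`` times; summarize attrition.

    Returns a DataFrame with one row per cascade stage (mean, sd of the
    surviving counts) plus a ``causal_retained`` rate row.  Replicate seeds
    are spawned deterministically from ``cfg.seed``.
    """
    import pandas as pd

    stage_counts: list[list[int]] = []
    stage_names: list[str] = []
    retained = 0
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_reps) % (2**31)
    for rep in range(n_reps):
        rep_cfg = SimConfig(**{**cfg.__dict__, "seed": int(seeds[rep])})
        exomes, _, truth = simulate_cohort(rep_cfg)
        by_id = {e.sample_id: e for e in exomes}
        ped = rep_cfg.pedigree
        affect = [e for e in exomes if e.status == "affected"]
        ctrls = [e for e in exomes if e.status == "unaffected"]
        final, trace = run_cascade(
            affect, ctrls, [], db_from_simulation(exomes), cascade_cfg
        )
        if not stage_names:
            stage_names = [name for name, _ in trace.stages]
        stage_counts.append(trace.counts())
        if truth.causal_key in final:
            retained += 1
    arr = np.array(stage_counts, dtype=float)
    out = pd.DataFrame(
        {
            "stage": stage_names,
            "mean_surviving": arr.mean(axis=0),
            "sd_surviving": arr.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(arr.shape[1]),
        }
    )
    out.attrs["causal_retention_rate"] = retained / n_reps
    out.attrs["n_reps"] = n_reps
    return out
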