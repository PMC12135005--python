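"""Coalescent simulation of haplotypes with known (true) mutation ages.

Two demographic models are supported:

* ``simple`` — a single constant-size population (defaults: diploid
  Ne = 10,000, mu = 1e-8 per bp per generation), a facsimile of a
  chromosome-22-sized neutral panmictic history;
* ``complex`` — the three-population out-of-Africa expansion model of
  Gutenkunst et al. (2009) (YRI/CEU/CHB with exponential growth in the
  non-African demes; defaults: ancestral Ne = 7,300, mu = 2.35e-8), with all
  genomes sampled from the CEU-like deme.

Simulation runs through msprime with a binary 0/1 mutation model so every
mutation's ancestral/derived polarity is known exactly; no mispolarization or
sequencing error is injected. True mutation ages (generations before present)
are read from the recorded mutation times of the simulated ancestral
recombination graph. Sites hit by more than one mutation violate the
infinite-sites assumption of the downstream estimators and are removed by
:func:`exclude_recurrent_sites`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
import tskit

from ._rng import rng_for, subseed
from .haplotypes import HaplotypeDataset, write_haplotype_vcf
from .intervals import GeneticMap

__all__ = [
    "ModelConfig",
    "SimulationResult",
    "simulate",
    "extract_true_ages",
    "exclude_recurrent_sites",
    "write_vcf",
    "write_true_ages",
    "read_true_ages",
    "watterson_expected_segsites",
]

logger = logging.getLogger(__name__)

TRUE_AGE_COLUMNS = ["position", "derived_count", "true_age_gen"]

# Gutenkunst et al. (2009) three-population out-of-Africa parameterization
# (times in generations, sizes diploid). The ancestral size is taken from the
# model config so the published value (7,300) lives in ModelConfig defaults.
_OOA = dict(
    N_AF=12_300,
    N_B=2_100,
    N_EU0=1_000,
    N_AS0=510,
    r_EU=0.004,
    r_AS=0.0055,
    T_AF=8_800,
    T_B=5_600,
    T_EU_AS=848,
    m_AF_B=25e-5,
    m_AF_EU=3e-5,
    m_AF_AS=1.9e-5,
    m_EU_AS=9.6e-5,
)


@dataclass
class ModelConfig:
    """Configuration of one simulated dataset.

    ``n_genomes`` counts sampled haploid genomes (two per diploid individual;
    must be even so the VCF export can pair them). ``ne`` is the constant
    diploid size under the simple model and the ancestral size under the
    complex model. Recombination comes from ``genetic_map`` when given, else
    from the flat ``flat_recomb_rate`` (per bp per generation).
    """

    model_id: str = "simple"
    n_genomes: int = 100
    seq_length_bp: int = 1_000_000
    mu: float = 1e-8
    ne: float = 10_000.0
    genetic_map: GeneticMap | None = None
    flat_recomb_rate: float = 1e-8
    seed: int = 1
    chrom: str = "22"

    def __post_init__(self):
        if self.model_id not in ("simple", "complex"):
            raise ValueError(f"unsupported model_id: {self.model_id!r}")
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_genomes % 2 != 0:
            raise ValueError("n_genomes must be even (diploid sampling)")
        if self.seq_length_bp < 1:
            raise ValueError("seq_length_bp must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.ne <= 0:
            raise ValueError("ne must be > 0")

    def echo_lines(self) -> list[str]:
        """Key=value snapshot for config-echo files and manifests."""
        return [
            f"model_id={self.model_id}",
            f"n_genomes={self.n_genomes}",
            f"seq_length_bp={self.seq_length_bp}",
            f"mu={self.mu!r}",
            f"ne={self.ne!r}",
            f"genetic_map={'anchors:%d' % len(self.genetic_map.positions_bp) if self.genetic_map else 'flat'}",
            f"flat_recomb_rate={self.flat_recomb_rate!r}",
            f"seed={self.seed}",
            f"chrom={self.chrom}",
        ]


@dataclass
class SimulationResult:
    """Haplotypes plus the matching truth table (one age per variant)."""

    haplotypes: HaplotypeDataset
    true_ages: pd.DataFrame  # columns: position, derived_count, true_age_gen
    config_echo: ModelConfig
    mutation_counts: np.ndarray = field(default=None)  # mutation events per site

    def __post_init__(self):
        if list(self.true_ages.columns) != TRUE_AGE_COLUMNS:
            raise ValueError(f"true-age table must have columns {TRUE_AGE_COLUMNS}")
        if self.mutation_counts is None:
            self.mutation_counts = np.ones(self.haplotypes.n_sites, dtype=np.int64)
        if len(self.true_ages) != self.haplotypes.n_sites:
            raise ValueError("every variant needs exactly one true-age row")
        if not np.array_equal(
            self.true_ages["position"].to_numpy(), self.haplotypes.positions
        ):
            raise ValueError("true-age positions must match the haplotype positions")


def _ooa_demography(ancestral_ne: float) -> msprime.Demography:
    """Three-population out-of-Africa demography, sampled deme ``CEU``."""
    p = _OOA
    d = msprime.Demography()
    d.add_population(name="YRI", initial_size=p["N_AF"])
    d.add_population(
        name="CEU",
        initial_size=p["N_EU0"] * math.exp(p["r_EU"] * p["T_EU_AS"]),
        growth_rate=p["r_EU"],
    )
    d.add_population(
        name="CHB",
        initial_size=p["N_AS0"] * math.exp(p["r_AS"] * p["T_EU_AS"]),
        growth_rate=p["r_AS"],
    )
    d.set_symmetric_migration_rate(["YRI", "CEU"], p["m_AF_EU"])
    d.set_symmetric_migration_rate(["YRI", "CHB"], p["m_AF_AS"])
    d.set_symmetric_migration_rate(["CEU", "CHB"], p["m_EU_AS"])
    # CEU/CHB split: CHB folds back into the bottleneck population B (= CEU here)
    d.add_mass_migration(time=p["T_EU_AS"], source="CHB", dest="CEU", proportion=1.0)
    d.add_migration_rate_change(time=p["T_EU_AS"], rate=0.0)
    d.add_symmetric_migration_rate_change(
        time=p["T_EU_AS"], populations=["YRI", "CEU"], rate=p["m_AF_B"]
    )
    d.add_population_parameters_change(
        time=p["T_EU_AS"], population="CEU", initial_size=p["N_B"], growth_rate=0.0
    )
    # out-of-Africa split: B folds back into the African population
    d.add_mass_migration(time=p["T_B"], source="CEU", dest="YRI", proportion=1.0)
    d.add_migration_rate_change(time=p["T_B"], rate=0.0)
    # ancestral size change
    d.add_population_parameters_change(
        time=p["T_AF"], population="YRI", initial_size=ancestral_ne
    )
    d.sort_events()
    return d


def _simulate_tree_sequence(config: ModelConfig) -> tskit.TreeSequence:
    n_ind = config.n_genomes // 2
    if config.genetic_map is not None:
        recomb = config.genetic_map.to_msprime_ratemap(config.seq_length_bp)
        seq_kwargs = {}
    else:
        recomb = config.flat_recomb_rate
        seq_kwargs = {"sequence_length": config.seq_length_bp}
    if config.model_id == "simple":
        demography = None
        samples = n_ind
        pop_kwargs = {"population_size": config.ne}
    else:
        demography = _ooa_demography(config.ne)
        samples = {"CEU": n_ind}
        pop_kwargs = {"demography": demography}
    ts = msprime.sim_ancestry(
        samples=samples,
        recombination_rate=recomb,
        ploidy=2,
        random_seed=subseed(config.seed, "ancestry"),
        **seq_kwargs,
        **pop_kwargs,
    )
    return msprime.sim_mutations(
        ts,
        rate=config.mu,
        model=msprime.BinaryMutationModel(),
        random_seed=subseed(config.seed, "mutations"),
    )


def extract_true_ages(
    ts: tskit.TreeSequence, seed: int = 0
) -> pd.DataFrame:
    """Per-site true mutation ages (generations) from a mutated tree sequence.

    The age is the simulator-recorded mutation time. If a mutation carries no
    recorded time, it is drawn uniformly on its branch interval (seeded).
    Multi-hit sites report the oldest mutation's time; they are flagged for
    removal by :func:`exclude_recurrent_sites` via the mutation count.
    Returns one row per site with columns position / n_mutations / true_age_gen
    (derived counts are attached by :func:`simulate`).
    """
    rng = rng_for(seed, "branch-age")
    rows = []
    tree = None
    for site in ts.sites():
        ages = []
        for mut in site.mutations:
            t = mut.time
            if tskit.is_unknown_time(t):
                if tree is None or not (tree.interval.left <= site.position < tree.interval.right):
                    tree = ts.at(site.position)
                child_t = ts.node(mut.node).time
                parent = tree.parent(mut.node)
                parent_t = ts.node(parent).time if parent != tskit.NULL else child_t
                t = float(rng.uniform(child_t, parent_t)) if parent_t > child_t else child_t
            ages.append(float(t))
        rows.append((int(site.position) + 1, len(site.mutations), max(ages)))
    return pd.DataFrame(rows, columns=["position", "n_mutations", "true_age_gen"])


def simulate(config: ModelConfig) -> SimulationResult:
    """Simulate haplotypes and true ages under ``config``.

    Deterministic: identical config (including seed) reproduces the identical
    result. Non-segregating sites (derived count 0 or n, possible through
    back mutation) are dropped; multi-hit sites are retained with their
    mutation count recorded, for :func:`exclude_recurrent_sites` to remove.
    """
    mts = _simulate_tree_sequence(config)
    n = config.n_genomes
    age_table = extract_true_ages(mts, seed=subseed(config.seed, "ages"))
    columns: list[np.ndarray] = []
    keep_rows: list[int] = []
    derived_counts: list[int] = []
    for i, var in enumerate(mts.variants()):
        anc = var.site.ancestral_state
        derived_mask = np.array(
            [a is not None and a != anc for a in var.alleles], dtype=bool
        )
        col = derived_mask[var.genotypes].astype(np.uint8)
        k = int(col.sum())
        if k == 0 or k == n:
            continue
        columns.append(col)
        keep_rows.append(i)
        derived_counts.append(k)
    if columns:
        matrix = np.column_stack(columns)
        kept = age_table.iloc[keep_rows].reset_index(drop=True)
        positions = kept["position"].to_numpy(dtype=np.int64)
        counts = kept["n_mutations"].to_numpy(dtype=np.int64)
        ages = kept["true_age_gen"].to_numpy()
    else:
        matrix = np.zeros((n, 0), dtype=np.uint8)
        positions = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
        ages = np.empty(0, dtype=float)
    ds = HaplotypeDataset(
        haplotypes=matrix,
        positions=positions,
        seq_length_bp=config.seq_length_bp,
        chrom=config.chrom,
        ploidy=2,
    )
    truth = pd.DataFrame(
        {
            "position": positions,
            "derived_count": np.asarray(derived_counts, dtype=np.int64),
            "true_age_gen": ages,
        }
    )
    logger.info(
        "simulate: model=%s n_genomes=%d L=%d seed=%d -> %d segregating sites "
        "(%d multi-hit)",
        config.model_id,
        config.n_genomes,
        config.seq_length_bp,
        config.seed,
        ds.n_sites,
        int((counts > 1).sum()),
    )
    return SimulationResult(
        haplotypes=ds, true_ages=truth, config_echo=config, mutation_counts=counts
    )


def exclude_recurrent_sites(result: SimulationResult) -> SimulationResult:
    """Drop every site hit by more than one mutation event.

    Retained sites are strictly biallelic single-origin mutations, matching
    the infinite-sites assumption of the age estimators.
    """
    keep = result.mutation_counts == 1
    if keep.all():
        return result
    ds = result.haplotypes.subset_sites(keep)
    truth = result.true_ages.loc[keep].reset_index(drop=True)
    logger.info(
        "exclude_recurrent_sites: removed %d multi-hit sites, %d retained",
        int((~keep).sum()),
        ds.n_sites,
    )
    return replace(
        result,
        haplotypes=ds,
        true_ages=truth,
        mutation_counts=result.mutation_counts[keep],
    )


def write_vcf(result: SimulationResult, path, ploidy: int = 2) -> None:
    """Write the simulated haplotypes as a phased VCF (REF ancestral, ALT derived)."""
    ds = result.haplotypes
    if ploidy != ds.ploidy:
        ds = replace(ds, ploidy=ploidy)
    write_haplotype_vcf(ds, path)


def write_true_ages(true_ages: pd.DataFrame, path) -> None:
    true_ages.to_csv(path, sep="\t", index=False, columns=TRUE_AGE_COLUMNS)


def read_true_ages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUE_AGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"true-age table is missing columns {sorted(missing)}")
    return df[TRUE_AGE_COLUMNS]


def watterson_expected_segsites(
    n_genomes: int, ne: float, mu: float, seq_length_bp: int
) -> float:
    """Closed-form Watterson expectation 4*Ne*mu*L*sum_{i<n} 1/i."""
    a_n = sum(1.0 / i for i in range(1, n_genomes))
    return 4.0 * ne * mu * seq_length_bp * a_n
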