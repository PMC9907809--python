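"""Competitive-growth screen simulator with multinomial sequencing sampling.

The generator emulates pooled selections of a site-saturated library:

* every amino-acid variant carries an abstract signaling activity ``a``
  (WT = 1; synonymous = 1; nonsense = 0, except truncations at the two most
  C-terminal library positions, which remove nothing functional and keep
  ``a = 1``; missense activities are drawn from a neutral-majority mixture or
  planted explicitly);
* a screen design maps activity to relative fitness ``w`` during selection
  (toxicity selection under lipoprotein-transport depletion: signaling is
  near-lethal, ``w = 1 - s_tox*min(a, 1)``; lactose selection: growth scales
  with reporter expression, ``w = w0 + k*a``; control cultures are neutral,
  ``w = 1`` for everyone);
* competitive outgrowth for ``G`` generations is deterministic exponential
  doubling, ``n_i(G) = n_i(0) * 2**(G * w_i)``;
* stochasticity enters through the inoculum bottleneck (founder cells drawn
  multinomially at the configured inoculum density) and through sequencing
  (multinomial reads at the configured depth).

Defaults follow the three published screen designs: ~11 generations from
1e5 cells/mL for the toxicity and long lactose selections, ~6 generations
from 1e7 cells/mL for the short lactose selection, triplicate cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .counting import AACountTable
from .enrichment import EnrichmentRecord, score_screen
from .library import (
    CODONS_ALL,
    LibraryDesign,
    ResidueVariant,
    build_library,
    parse_variant_name,
    translate_codon,
)

__all__ = [
    "synthetic_rcsf_cds",
    "default_library",
    "MissenseActivityModel",
    "ActivityProfile",
    "assign_activities",
    "FitnessModel",
    "lof_im_model",
    "gof_om_model",
    "lof_om_model",
    "SimConfig",
    "simulate_pool",
    "sequence_pool",
    "ScreenData",
    "generate_screen",
    "run_screen",
]

# Residues of the sensory lipoprotein fixed at their published positions so
# that named alleles (A55K, T132I, ...) exist in the default library. The
# remaining residues are an arbitrary fixed filler: this CDS is a SYNTHETIC
# stand-in, not the real gene sequence.
_PINNED_RESIDUES = {
    1: "M",
    16: "C",  # lipidated N-terminal cysteine of the mature protein
    53: "T",
    55: "A",
    60: "G",
    62: "P",
    64: "R",
    74: "C",
    78: "N",
    107: "H",
    109: "C",
    118: "C",
    124: "C",
    127: "S",
    132: "T",
}
_PROTEIN_LENGTH = 134

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (alphabetically first in the standard code)
_CODON_FOR_AA = {}
for _codon in CODONS_ALL:
    _aa = translate_codon(_codon)
    if _aa != "*" and _aa not in _CODON_FOR_AA:
        _CODON_FOR_AA[_aa] = _codon


def synthetic_rcsf_cds() -> str:
    """Deterministic synthetic stand-in CDS for the sensory lipoprotein.

    134 codons, no stop. Residues named in the mutant analysis are pinned at
    their published positions; everything else is arbitrary but fixed. This
    is a synthetic sequence for simulation and testing, not the real gene.
    """
    rng = np.random.default_rng(7)
    protein = [
        _PINNED_RESIDUES.get(pos, _AA20[rng.integers(len(_AA20))])
        for pos in range(1, _PROTEIN_LENGTH + 1)
    ]
    return "".join(_CODON_FOR_AA[aa] for aa in protein)


def default_library(codon_alphabet: str = "all") -> LibraryDesign:
    """The default simulated library: residues 50-134 of the synthetic CDS."""
    return build_library(synthetic_rcsf_cds(), 50, 134, codon_alphabet)


@dataclass(frozen=True)
class MissenseActivityModel:
    """Neutral-majority mixture for missense signaling activities.

    Most substitutions leave signaling intact (point mass at ``a = 1``); a
    loss-of-function tail draws activities uniformly from ``lof_range`` and a
    rarer gain-of-function tail from ``gof_range``.
    """

    p_neutral: float = 0.75
    p_lof: float = 0.20
    p_gof: float = 0.05
    lof_range: tuple[float, float] = (0.0, 0.6)
    gof_range: tuple[float, float] = (1.2, 2.0)

    def __post_init__(self) -> None:
        total = self.p_neutral + self.p_lof + self.p_gof
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")
        if min(self.p_neutral, self.p_lof, self.p_gof) < 0:
            raise ValueError("mixture probabilities must be non-negative")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        component = rng.choice(
            3, size=size, p=[self.p_neutral, self.p_lof, self.p_gof]
        )
        out = np.ones(size)
        lof = component == 1
        gof = component == 2
        out[lof] = rng.uniform(*self.lof_range, size=int(lof.sum()))
        out[gof] = rng.uniform(*self.gof_range, size=int(gof.sum()))
        return out

    def to_dict(self) -> dict:
        return {
            "p_neutral": self.p_neutral,
            "p_lof": self.p_lof,
            "p_gof": self.p_gof,
            "lof_range": list(self.lof_range),
            "gof_range": list(self.gof_range),
        }


@dataclass
class ActivityProfile:
    """Signaling activity per amino-acid variant (WT activity = 1)."""

    activities: dict[ResidueVariant, float]
    wt_activity: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.activities.values()):
            raise ValueError("activities must be non-negative")
        for v in self.activities:
            if v.vclass == "synonymous" and self.activities[v] != self.wt_activity:
                raise ValueError(
                    f"synonymous variant {v.name} must have WT activity"
                )

    def activity(self, variant: ResidueVariant) -> float:
        return self.activities[variant]


def assign_activities(
    library: LibraryDesign,
    planted: dict | None = None,
    rng: np.random.Generator | int | None = None,
    missense_model: MissenseActivityModel | None = None,
    neutral_cterm_truncations: int = 2,
) -> ActivityProfile:
    """Build the activity profile for a library.

    ``planted`` maps variants (or their names) to explicit activities and
    overrides the class defaults; synonymous variants cannot be planted away
    from WT activity. Deterministic given the rng seed.
    """
    rng = np.random.default_rng(rng)
    model = missense_model or MissenseActivityModel()
    variants = library.aa_variants()
    missense = [v for v in variants if v.vclass == "missense"]
    sampled = dict(zip(missense, model.sample(rng, len(missense))))
    cterm_floor = library.residue_end - neutral_cterm_truncations + 1

    activities: dict[ResidueVariant, float] = {}
    for v in variants:
        if v.vclass == "synonymous":
            activities[v] = 1.0
        elif v.vclass == "nonsense":
            # truncation at the extreme C-terminus removes nothing needed
            activities[v] = 1.0 if v.position >= cterm_floor else 0.0
        else:
            activities[v] = float(sampled[v])

    if planted:
        valid = set(variants)
        for key, a in planted.items():
            v = parse_variant_name(key, library) if isinstance(key, str) else key
            if v not in valid:
                raise ValueError(f"planted variant not in library: {v.name}")
            if v.vclass == "synonymous" and a != 1.0:
                raise ValueError("cannot plant a non-WT synonymous activity")
            activities[v] = float(a)
    return ActivityProfile(activities)


@dataclass(frozen=True)
class FitnessModel:
    """Map from signaling activity to relative fitness during selection.

    ``kind="lol_depletion"``: toxicity selection — signaling kills, so
    ``w = 1 - s_tox * min(a, 1)`` (``s_tox`` near 1 makes WT signaling
    near-lethal). ``kind="lactose"``: growth on lactose scales with reporter
    expression, ``w = w0 + k * a`` (signaling-null cells keep the basal
    ``w0 > 0``, so WT growth is low but detectable relative to activated
    mutants only through the activity term). Control cultures have ``w = 1``
    for every variant regardless of activity.
    """

    screen_id: str
    kind: str  # "lol_depletion" | "lactose"
    s_tox: float = 0.9
    w0: float = 0.2
    k: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("lol_depletion", "lactose"):
            raise ValueError(f"unknown fitness model kind: {self.kind!r}")

    def selective_fitness(self, activity) -> np.ndarray:
        a = np.asarray(activity, dtype=float)
        if self.kind == "lol_depletion":
            w = 1.0 - self.s_tox * np.minimum(a, 1.0)
        else:
            w = self.w0 + self.k * a
        if np.any(w < 0):
            raise ValueError("fitness model produced negative fitness")
        return w

    def control_fitness(self, activity) -> np.ndarray:
        return np.ones_like(np.asarray(activity, dtype=float))

    def to_dict(self) -> dict:
        d = {"screen_id": self.screen_id, "kind": self.kind}
        if self.kind == "lol_depletion":
            d["s_tox"] = self.s_tox
        else:
            d.update(w0=self.w0, k=self.k)
        return d


def lof_im_model(s_tox: float = 0.9) -> FitnessModel:
    """Toxicity selection (lipoprotein-transport depletion, -arabinose)."""
    return FitnessModel(screen_id="LOF_IM", kind="lol_depletion", s_tox=s_tox)


def gof_om_model(w0: float = 0.2, k: float = 0.8) -> FitnessModel:
    """Long lactose selection favouring gain-of-function sweeps."""
    return FitnessModel(screen_id="GOF_OM", kind="lactose", w0=w0, k=k)


def lof_om_model(w0: float = 0.2, k: float = 0.8) -> FitnessModel:
    """Short lactose selection discriminating signaling-defective variants."""
    return FitnessModel(screen_id="LOF_OM", kind="lactose", w0=w0, k=k)


_SCREEN_DEFAULTS = {
    # generations, inoculum cells/mL
    "LOF_IM": (11.0, 1e5),
    "GOF_OM": (11.0, 1e5),
    "LOF_OM": (6.0, 1e7),
}


@dataclass
class SimConfig:
    """Full specification of one simulated screen."""

    library: LibraryDesign
    activities: ActivityProfile
    fitness: FitnessModel
    generations: float
    inoculum_density: float  # cells/mL
    culture_volume_ml: float = 10.0
    depth: int = 1_000_000
    replicates: int = 3
    seed: int = 0
    founder_bottleneck: bool = True

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.inoculum_density <= 0 or self.culture_volume_ml <= 0:
            raise ValueError("inoculum density and volume must be positive")

    @property
    def inoculum_cells(self) -> int:
        return int(round(self.inoculum_density * self.culture_volume_ml))

    @classmethod
    def for_screen(
        cls,
        screen_id: str,
        library: LibraryDesign | None = None,
        activities: ActivityProfile | None = None,
        seed: int = 0,
        **overrides,
    ) -> "SimConfig":
        """Config with the published design defaults for one screen."""
        if screen_id not in _SCREEN_DEFAULTS:
            raise ValueError(f"unknown screen: {screen_id!r}")
        library = library or default_library()
        if activities is None:
            activities = assign_activities(
                library, rng=np.random.default_rng(seed)
            )
        generations, inoculum = _SCREEN_DEFAULTS[screen_id]
        fitness = {
            "LOF_IM": lof_im_model,
            "GOF_OM": gof_om_model,
            "LOF_OM": lof_om_model,
        }[screen_id]()
        cfg = cls(
            library=library,
            activities=activities,
            fitness=fitness,
            generations=generations,
            inoculum_density=inoculum,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def manifest(self) -> dict:
        return {
            "screen_id": self.fitness.screen_id,
            "fitness": self.fitness.to_dict(),
            "generations": self.generations,
            "inoculum_density": self.inoculum_density,
            "culture_volume_ml": self.culture_volume_ml,
            "depth": self.depth,
            "replicates": self.replicates,
            "seed": self.seed,
            "founder_bottleneck": self.founder_bottleneck,
            "library": {
                "residue_start": self.library.residue_start,
                "residue_end": self.library.residue_end,
                "n_codon_variants": len(self.library.variants()),
                "n_aa_variants": len(self.library.aa_variants()),
            },
        }


def simulate_pool(
    start_freq: np.ndarray, fitness: np.ndarray, generations: float
) -> np.ndarray:
    """Deterministic competitive outgrowth: ``n_i(G) = n_i(0) * 2**(G*w_i)``.

    Computed in log space so large generation-fitness products cannot
    overflow; returns normalised final frequencies.
    """
    start_freq = np.asarray(start_freq, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    if start_freq.shape != fitness.shape:
        raise ValueError("frequency and fitness vectors must align")
    if np.any(start_freq < 0) or start_freq.sum() <= 0:
        raise ValueError("starting frequencies must be non-negative, not all zero")
    if np.any(fitness < 0):
        raise ValueError("fitness must be non-negative")
    with np.errstate(divide="ignore"):
        log_n = np.where(
            start_freq > 0,
            np.log(start_freq, where=start_freq > 0, out=np.full_like(start_freq, -np.inf))
            + generations * fitness * np.log(2.0),
            -np.inf,
        )
    log_n -= log_n.max()
    n = np.exp(log_n)
    return n / n.sum()


def sequence_pool(
    frequencies: np.ndarray, depth: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Multinomial sequencing of a pool: counts summing to ``depth``."""
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("frequencies must sum to 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(rng)
    return rng.multinomial(depth, p / total)


@dataclass
class ScreenData:
    """Output of one simulated screen: paired count tables plus a manifest."""

    selective: list[AACountTable]
    control: list[AACountTable]
    manifest: dict


def _counts_table(
    variants: list[ResidueVariant],
    counts: np.ndarray,
    sample_id: str,
    condition: str,
    replicate: int,
    depth: int,
) -> AACountTable:
    # counts[:-1] are variants, counts[-1] is WT; zeros are omitted so that
    # written tables round-trip exactly
    aa_counts = {
        v: int(c) for v, c in zip(variants, counts[:-1]) if c > 0
    }
    return AACountTable(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        aa_counts=aa_counts,
        wt_count=int(counts[-1]),
        total_reads=depth,
    )


def generate_screen(config: SimConfig) -> ScreenData:
    """Simulate triplicate (by default) selective + control cultures.

    Each replicate culture is founded by a multinomial draw of inoculum
    cells from the (uniform by default) library pool, grown deterministically
    (neutrally in the control), and sequenced multinomially at the configured
    depth. Per-replicate random streams are spawned from the master seed, so
    identical configs produce byte-identical tables.
    """
    library = config.library
    variants = library.aa_variants()
    n = len(variants) + 1  # + WT
    start = np.full(n, 1.0 / n)
    a = np.array(
        [config.activities.activity(v) for v in variants]
        + [config.activities.wt_activity]
    )
    w_sel = config.fitness.selective_fitness(a)
    screen = config.fitness.screen_id

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.replicates)
    selective: list[AACountTable] = []
    control: list[AACountTable] = []
    for r, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        for condition, w in (("control", None), ("selective", w_sel)):
            if config.founder_bottleneck:
                founders = rng.multinomial(config.inoculum_cells, start)
                f0 = founders / founders.sum()
            else:
                f0 = start
            final = f0 if w is None else simulate_pool(f0, w, config.generations)
            counts = sequence_pool(final, config.depth, rng)
            table = _counts_table(
                variants,
                counts,
                sample_id=f"{screen}_{condition}_r{r}",
                condition=condition,
                replicate=r,
                depth=config.depth,
            )
            (control if condition == "control" else selective).append(table)
    return ScreenData(
        selective=selective, control=control, manifest=config.manifest()
    )


def run_screen(
    config: SimConfig, floor_reads: float = 2, combine: str = "mean"
) -> tuple[ScreenData, list[EnrichmentRecord]]:
    """Simulate a screen and score it end to end."""
    data = generate_screen(config)
    records = score_screen(
        data.selective, data.control, floor_reads=floor_reads, combine=combine
    )
    return data, records
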