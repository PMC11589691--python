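"""Synthetic five-river, two-ecotype dataset generator with planted selection.

The generator emulates the sampling design of a paired above/below-falls
study: an ancestral population splits into five river (anadromous) demes
that exchange migrants; within each river a resident deme is founded by a
bottleneck at the falls split, after which residents evolve in isolation
(optional one-way resident-to-anadromous seepage). Per-window selection
regimes can be planted:

* ``DIVERGENT_BOTH`` — opposing directional selection between ecotypes
  (migration-propensity loci),
* ``SWEEP_ANAD``     — directional selection in anadromous demes only
  (migratory-lifestyle loci),
* ``SWEEP_RES``      — directional selection in resident demes only
  (residency loci),
* ``BALANCED_ANAD``  — heterozygote advantage in anadromous demes and
  directional selection against the balanced allele in residents.

Each 10 kb window is simulated independently (free recombination between
windows). Fully neutral windows use msprime's discrete-time Wright-Fisher
model under the identical demography; windows with planted selection run
through an in-package forward Wright-Fisher engine (viability selection,
recombination, infinite-sites mutation) whose ancestral standing variation
is itself drawn from an msprime simulation, so background variation is
statistically consistent across the two routes. Everything is
deterministic given the master seed.

Default parameter values are scaled for desk-size experiments: small deme
sizes, short split times and correspondingly strong selection
coefficients, with the mutation rate chosen so that 4*Ne*mu matches a
per-site Watterson theta of ~0.9e-3 in the anadromous demes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, PopulationPanel, ValidationError

REGIMES = ("NEUTRAL", "DIVERGENT_BOTH", "SWEEP_ANAD", "SWEEP_RES", "BALANCED_ANAD")
_RIVER_NAMES = ["CT", "EF", "RO", "RY", "WE"]
_BASES = "ACGT"


@dataclass
class DemographyConfig:
    """Demography and genome layout of the synthetic study system."""

    n_rivers: int = 5
    Ne_ancestral: int = 500
    Ne_anadromous: int = 500
    Ne_resident: int = 100
    T_river_split: int = 400  # generations ago
    T_falls_split: int = 200
    migration_anadromous: float = 0.005
    seepage_resident_to_anadromous: float = 0.0
    samples_per_population: int = 20
    n_chromosomes: int = 5
    windows_per_chromosome: int = 1_000
    window_length: int = 10_000
    mutation_rate: float = 4.5e-7
    recombination_rate: float = 1e-7
    # age of the balanced polymorphism (generations): stem mutations
    # accumulated since the two allelic classes diverged
    balanced_allele_age: int = 4_000
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.migration_anadromous, self.seepage_resident_to_anadromous):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.T_river_split <= self.T_falls_split or self.T_falls_split <= 0:
            raise ValidationError("need T_river_split > T_falls_split > 0")
        if min(self.Ne_ancestral, self.Ne_anadromous, self.Ne_resident) < 10:
            raise ValidationError("Ne must be >= 10")

    @property
    def rivers(self) -> list[str]:
        if self.n_rivers <= len(_RIVER_NAMES):
            return _RIVER_NAMES[: self.n_rivers]
        return _RIVER_NAMES + [f"RV{i}" for i in range(len(_RIVER_NAMES), self.n_rivers)]

    @property
    def n_windows(self) -> int:
        return self.n_chromosomes * self.windows_per_chromosome

    @property
    def windows_per_contig(self) -> list[int]:
        """Chromosome sizes taper (like real karyotypes) while keeping the total."""
        n = self.n_chromosomes
        if n == 1:
            return [self.windows_per_chromosome]
        weights = np.linspace(1.4, 0.6, n)
        weights *= n / weights.sum()
        counts = np.maximum(1, np.round(self.windows_per_chromosome * weights).astype(int))
        counts[-1] += self.n_windows - counts.sum()
        return [int(c) for c in counts]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": c * self.window_length
            for i, c in enumerate(self.windows_per_contig)
        }


@dataclass(frozen=True)
class PlantedLocus:
    window_index: int  # global window index (chromosome-major order)
    regime: str
    s: float
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")


@dataclass
class SelectionPlan:
    loci: list[PlantedLocus] = field(default_factory=list)

    def regime_of(self) -> dict[int, PlantedLocus]:
        out = {}
        for locus in self.loci:
            if locus.window_index in out:
                raise ValidationError(f"window {locus.window_index} planted twice")
            out[locus.window_index] = locus
        return out


DEFAULT_S = {
    "DIVERGENT_BOTH": 0.5,
    "SWEEP_ANAD": 0.5,
    "SWEEP_RES": 0.5,
    "BALANCED_ANAD": 0.5,
}


def default_selection_plan(config: DemographyConfig, per_regime: int = 12) -> SelectionPlan:
    """Evenly spaced planted windows, regimes interleaved, default s and h."""
    regimes = [r for r in REGIMES if r != "NEUTRAL"]
    n_planted = per_regime * len(regimes)
    if n_planted > config.n_windows:
        raise ValidationError("more planted loci than windows")
    loci = []
    for j in range(n_planted):
        idx = int((j + 0.5) * config.n_windows / n_planted)
        regime = regimes[j % len(regimes)]
        loci.append(PlantedLocus(window_index=idx, regime=regime, s=DEFAULT_S[regime]))
    return SelectionPlan(loci)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    mask: list[tuple[str, int, int]]
    panel: PopulationPanel
    truth: pd.DataFrame
    contig_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def _build_panel(config: DemographyConfig) -> PopulationPanel:
    rows = []
    for river in config.rivers:
        for eco in ("A", "R"):
            for i in range(config.samples_per_population):
                rows.append(
                    (f"{river}_{eco}_{i:02d}", river, eco, "F" if i % 2 == 0 else "M")
                )
    return PopulationPanel(pd.DataFrame(rows, columns=["sample", "river", "ecotype", "sex"]))


# ---------------------------------------------------------------------------
# msprime building blocks
# ---------------------------------------------------------------------------


def _msprime_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 2)) + 1


def _build_demography(config: DemographyConfig):
    import msprime

    d = msprime.Demography()
    d.add_population(name="ANC", initial_size=config.Ne_ancestral)
    a_names = [f"A_{r}" for r in config.rivers]
    r_names = [f"R_{r}" for r in config.rivers]
    for name in a_names:
        d.add_population(name=name, initial_size=config.Ne_anadromous)
    for name in r_names:
        d.add_population(name=name, initial_size=config.Ne_resident)
    if config.n_rivers > 1 and config.migration_anadromous > 0:
        d.set_symmetric_migration_rate(a_names, config.migration_anadromous)
    if config.seepage_resident_to_anadromous > 0:
        # forward-time resident -> anadromous flow: backwards, lineages now in
        # A trace back into R
        for a, r in zip(a_names, r_names):
            d.set_migration_rate(source=a, dest=r, rate=config.seepage_resident_to_anadromous)
    for a, r in zip(a_names, r_names):
        d.add_population_split(time=config.T_falls_split, derived=[r], ancestral=a)
    d.add_population_split(time=config.T_river_split, derived=a_names, ancestral="ANC")
    d.sort_events()
    return d


def _neutral_window(config: DemographyConfig, ss: np.random.SeedSequence):
    """One fully neutral window: positions (local) and diploid alt dosages."""
    import msprime

    demography = _build_demography(config)
    samples = []
    for river in config.rivers:
        samples.append(msprime.SampleSet(config.samples_per_population, population=f"A_{river}"))
        samples.append(msprime.SampleSet(config.samples_per_population, population=f"R_{river}"))
    s1, s2 = ss.spawn(2)
    models = [
        # exact generation-by-generation dynamics through the structured phase,
        # standard coalescent for the deep ancestral history
        msprime.DiscreteTimeWrightFisher(duration=config.T_river_split + 10),
        msprime.StandardCoalescent(),
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=config.window_length,
        recombination_rate=config.recombination_rate,
        model=models,
        random_seed=_msprime_seed(s1),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=_msprime_seed(s2),
    )
    H = ts.genotype_matrix()  # (sites, haplotypes) in {0,1}
    pos = ts.tables.sites.position.astype(np.int64)
    dos = (H[:, ::2] + H[:, 1::2]).astype(np.int8)  # (sites, individuals)
    seg = (dos.sum(axis=1) > 0) & (dos.sum(axis=1) < 2 * dos.shape[1])
    return pos[seg], dos[seg]


def _ancestral_haplotypes(config: DemographyConfig, ss: np.random.SeedSequence):
    """Standing variation of the whole ancestral population (2*Ne haplotypes)."""
    import msprime

    s1, s2 = ss.spawn(2)
    ts = msprime.sim_ancestry(
        samples=config.Ne_ancestral,
        population_size=config.Ne_ancestral,
        sequence_length=config.window_length,
        recombination_rate=config.recombination_rate,
        model=[msprime.DiscreteTimeWrightFisher(duration=200), msprime.StandardCoalescent()],
        random_seed=_msprime_seed(s1),
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, model=msprime.BinaryMutationModel(),
        random_seed=_msprime_seed(s2),
    )
    H = np.ascontiguousarray(ts.genotype_matrix().T.astype(np.uint8))  # (2Ne, S)
    pos = ts.tables.sites.position.astype(np.int64)
    return H, pos


# ---------------------------------------------------------------------------
# forward Wright-Fisher engine (selection windows)
# ---------------------------------------------------------------------------


def _fitness_tables(regime: str, s: float, h: float):
    """Per-ecotype selection rule: (focal attribute, genotype fitness table).

    The focal attribute names which planted allele the deme's viability
    selection reads ("focal_x" or "focal_y"); opposing directional
    selection uses two young alleles on different haplotype backgrounds,
    one favoured per ecotype, so both pools sweep.
    """
    favored = np.array([1.0, 1.0 + h * s, 1.0 + s])
    disfavored = np.array([1.0, 1.0 - h * s, 1.0 - s])
    # asymmetric heterozygote advantage: equilibrium focal frequency 2/3,
    # so the balance tips toward one variant where it is maintained
    overdominant = np.array([1.0 - s, 1.0 + s, 1.0])
    if regime == "DIVERGENT_BOTH":
        return ("focal_x", favored), ("focal_y", favored)
    if regime == "SWEEP_ANAD":
        return ("focal_x", favored), None
    if regime == "SWEEP_RES":
        return None, ("focal_x", favored)
    if regime == "BALANCED_ANAD":
        return ("focal_x", overdominant), ("focal_x", disfavored)
    return None, None


class _ForwardWindow:
    """Forward diploid Wright-Fisher simulation of one window across demes.

    Haplotypes of each deme are rows of a uint8 matrix sharing a global
    column (site) registry; columns are kept unsorted during the run and
    ordered once at sampling time.
    """

    def __init__(self, config: DemographyConfig, locus: PlantedLocus, rng: np.random.Generator):
        self.cfg = config
        self.locus = locus
        self.rng = rng
        self.L = config.window_length
        self.positions = np.empty(0, dtype=np.int64)
        self.demes: dict[str, np.ndarray] = {}
        self.focal_x = -1  # primary planted allele (column index)
        self.focal_y = -1  # second allele of an opposing-selection pair
        self.p_crossover = min(1.0, config.recombination_rate * (self.L - 1))

    # -- gamete formation ---------------------------------------------------

    def _gametes(self, H: np.ndarray, parents: np.ndarray) -> np.ndarray:
        """One recombinant gamete per entry of ``parents`` (individual ids)."""
        rng = self.rng
        n = len(parents)
        a = rng.integers(0, 2, size=n)
        out = H[2 * parents + a].copy()
        if self.p_crossover > 0:
            rec = np.flatnonzero(rng.random(n) < self.p_crossover)
            for i in rec:
                bp = rng.integers(1, self.L)
                mask = self.positions >= bp
                out[i, mask] = H[2 * parents[i] + 1 - a[i], mask]
        return out

    def _offspring(self, source_H: np.ndarray, n_out: int, selection) -> np.ndarray:
        """A full offspring generation (2*n_out haplotype rows).

        ``selection`` is None (neutral) or a (focal attribute, fitness
        table) pair; viability selection weights parents by their genotype
        at that focal column.
        """
        n_src = source_H.shape[0] // 2
        w = None
        if selection is not None:
            col = getattr(self, selection[0])
            if col >= 0:
                g = source_H[::2, col].astype(np.int64) + source_H[1::2, col]
                wv = selection[1][g]
                tot = wv.sum()
                w = wv / tot if tot > 0 else None
        parents = self.rng.choice(n_src, size=2 * n_out, replace=True, p=w)
        gam = self._gametes(source_H, parents)
        # rows 2i, 2i+1 are the two gametes of individual i
        return gam

    # -- per-generation bookkeeping ------------------------------------------

    def _mutate(self) -> None:
        rng = self.rng
        total_haps = sum(H.shape[0] for H in self.demes.values())
        n_new = rng.poisson(total_haps * self.cfg.mutation_rate * self.L)
        if n_new == 0:
            return
        existing = set(self.positions.tolist())
        new_pos = []
        while len(new_pos) < n_new:
            cand = int(rng.integers(0, self.L))
            if cand not in existing:
                existing.add(cand)
                new_pos.append(cand)
        names = list(self.demes)
        sizes = np.array([self.demes[d].shape[0] for d in names])
        carrier_deme = rng.choice(len(names), size=n_new, p=sizes / sizes.sum())
        carrier_row = rng.integers(0, sizes[carrier_deme])
        for d_i, name in enumerate(names):
            block = np.zeros((self.demes[name].shape[0], n_new), dtype=np.uint8)
            sel = carrier_deme == d_i
            block[carrier_row[sel], np.flatnonzero(sel)] = 1
            self.demes[name] = np.concatenate([self.demes[name], block], axis=1)
        self.positions = np.concatenate([self.positions, np.array(new_pos, dtype=np.int64)])

    def _prune(self) -> None:
        names = list(self.demes)
        tot = sum(self.demes[d].sum(axis=0, dtype=np.int64) for d in names)
        n_haps = sum(self.demes[d].shape[0] for d in names)
        keep = (tot > 0) & (tot < n_haps)
        for attr in ("focal_x", "focal_y"):
            if getattr(self, attr) >= 0:
                keep[getattr(self, attr)] = True
        if keep.all():
            return
        for d in names:
            self.demes[d] = np.ascontiguousarray(self.demes[d][:, keep])
        new_index = np.cumsum(keep) - 1
        for attr in ("focal_x", "focal_y"):
            old = getattr(self, attr)
            if old >= 0:
                setattr(self, attr, int(new_index[old]))
        self.positions = self.positions[keep]

    # -- focal allele ---------------------------------------------------------

    def _plant_young_allele(self, freq: float = 0.05, exclude_col: int = -1) -> int:
        """Plant the focal allele on a single copied haplotype background.

        One donor haplotype (shared by all demes — the allele arose once)
        is copied onto ``freq`` of every deme's haplotypes and the new
        allele is placed on those copies. At low ``freq`` this emulates a
        recent variant on one background, so directional selection
        produces a hard selective sweep in every selected deme: complete
        hitchhiking, diversity loss, a post-sweep excess of rare variants,
        and the same linked sites differentiated across the pool. At
        ``freq=0.5`` it creates a haplotype dimorphism whose many
        diagnostic sites heterozygote advantage then pins near frequency
        0.5. Donors and replaced rows avoid carriers of ``exclude_col`` so
        the two alleles of an opposing-selection pair ride different
        backgrounds.
        """
        pos = self.L // 2
        existing = set(self.positions.tolist())
        while pos in existing:
            pos += 1
        col_index = len(self.positions)
        names = list(self.demes)
        donor_deme = names[int(self.rng.integers(len(names)))]
        Hd = self.demes[donor_deme]
        rows = np.arange(Hd.shape[0])
        if exclude_col >= 0:
            rows = rows[Hd[:, exclude_col] == 0]
        donor_hap = Hd[int(self.rng.choice(rows))].copy()
        for name, H in list(self.demes.items()):
            n_haps = H.shape[0]
            targets = np.arange(n_haps)
            if exclude_col >= 0:
                targets = targets[H[:, exclude_col] == 0]
            k = max(1, int(round(freq * n_haps)))
            chosen = self.rng.choice(targets, size=min(k, len(targets)), replace=False)
            H = np.concatenate([H, np.zeros((n_haps, 1), dtype=np.uint8)], axis=1)
            H[chosen, :-1] = donor_hap
            H[chosen, -1] = 1
            self.demes[name] = H
        self.positions = np.concatenate([self.positions, [pos]])
        return col_index

    def _build_balanced_ancestor(self) -> None:
        """Replace the ancestral population with an ancient balanced dimorphism.

        Half the ancestral haplotypes are drawn from an independent
        coalescent simulation, emulating two allelic classes that diverged
        ``balanced_allele_age`` generations ago (the deep allelic genealogy
        of long-term balancing selection): the classes carry disjoint sets
        of class-specific segregating variants plus stem mutations fixed
        within one class, all of which heterozygote advantage keeps at
        intermediate frequency. The focal column marks class membership.
        """
        H1 = self.demes.pop("ANC")
        pos1 = self.positions
        H2, pos2 = _ancestral_haplotypes(
            self.cfg, np.random.SeedSequence(self.rng.integers(2**31 - 1))
        )
        # drop second-lineage sites whose positions collide with the first
        fresh = ~np.isin(pos2, pos1)
        H2 = H2[:, fresh]
        pos2 = pos2[fresh]
        half = (H1.shape[0] // 4) * 2  # even: keep diploid pairing intact
        focal_pos = self.L // 2
        taken = set(pos1.tolist()) | set(pos2.tolist())
        while focal_pos in taken:
            focal_pos += 1
        # stem mutations: fixed within one class, absent from the other
        n_stem = int(self.rng.poisson(self.cfg.mutation_rate * self.L * self.cfg.balanced_allele_age))
        stem_pos = []
        while len(stem_pos) < n_stem:
            cand = int(self.rng.integers(0, self.L))
            if cand not in taken:
                taken.add(cand)
                stem_pos.append(cand)
        stem_class = self.rng.integers(0, 2, size=n_stem)

        n1, n2 = H1.shape[1], H2.shape[1]
        stem_top = np.broadcast_to((stem_class == 0).astype(np.uint8), (half, n_stem))
        stem_bottom = np.broadcast_to((stem_class == 1).astype(np.uint8), (half, n_stem))
        top = np.concatenate(
            [H1[:half], np.zeros((half, n2), dtype=np.uint8), stem_top,
             np.zeros((half, 1), dtype=np.uint8)],
            axis=1,
        )
        bottom = np.concatenate(
            [np.zeros((half, n1), dtype=np.uint8), H2[:half], stem_bottom,
             np.ones((half, 1), dtype=np.uint8)],
            axis=1,
        )
        self.demes = {"ANC": np.concatenate([top, bottom], axis=0)}
        self.positions = np.concatenate(
            [pos1, pos2, np.array(stem_pos, dtype=np.int64), [focal_pos]]
        )
        self.focal_x = len(self.positions) - 1

    # -- demography ----------------------------------------------------------

    def run(self):
        cfg = self.cfg
        rng = self.rng
        regime = self.locus.regime
        fit_a, fit_r = _fitness_tables(regime, self.locus.s, self.locus.h)
        a_names = [f"A_{r}" for r in cfg.rivers]
        r_names = [f"R_{r}" for r in cfg.rivers]

        anc_H, anc_pos = _ancestral_haplotypes(cfg, np.random.SeedSequence(rng.integers(2**31 - 1)))
        self.positions = anc_pos
        self.demes = {"ANC": anc_H}
        if regime == "BALANCED_ANAD":
            self._build_balanced_ancestor()

        # found the river (anadromous) demes from the ancestral population
        anc = self.demes.pop("ANC")
        for name in a_names:
            self.demes[name] = self._offspring(anc, cfg.Ne_anadromous, None)
        del anc

        # phase 1: river demes only (balancing already acts in anadromous contexts)
        fit_phase1 = fit_a if regime == "BALANCED_ANAD" else None
        for _ in range(cfg.T_river_split - cfg.T_falls_split):
            self._generation(a_names, [], fit_phase1, None)

        # falls split: residents founded by a bottleneck from their river deme
        for a, r in zip(a_names, r_names):
            self.demes[r] = self._offspring(self.demes[a], cfg.Ne_resident, None)
        if regime in ("DIVERGENT_BOTH", "SWEEP_ANAD", "SWEEP_RES"):
            self.focal_x = self._plant_young_allele()
            if regime == "DIVERGENT_BOTH":
                self.focal_y = self._plant_young_allele(exclude_col=self.focal_x)

        # phase 2: both ecotypes, selection per regime
        for _ in range(cfg.T_falls_split):
            self._generation(a_names, r_names, fit_a, fit_r)

        return self._sample(a_names, r_names)

    def _generation(self, a_names, r_names, fit_a, fit_r) -> None:
        cfg = self.cfg
        rng = self.rng
        new = {}
        n_a = len(a_names)
        for name in a_names:
            # migrant offspring draw both parents from a random other A deme;
            # optional seepage draws them from the paired resident deme
            n_out = cfg.Ne_anadromous
            sources = np.full(n_out, -1, dtype=np.int64)  # -1: stay home
            if n_a > 1 and cfg.migration_anadromous > 0:
                mig = rng.random(n_out) < cfg.migration_anadromous
                others = [a for a in a_names if a != name]
                sources[mig] = rng.integers(0, len(others), size=int(mig.sum()))
            seep_name = None
            if r_names and cfg.seepage_resident_to_anadromous > 0:
                seep_name = "R_" + name.split("_", 1)[1]
                if seep_name in self.demes:
                    seep = (rng.random(n_out) < cfg.seepage_resident_to_anadromous) & (sources == -1)
                    sources[seep] = -2
            parts = []
            home = sources == -1
            if home.any():
                parts.append(self._offspring(self.demes[name], int(home.sum()), fit_a))
            if n_a > 1:
                others = [a for a in a_names if a != name]
                for k, other in enumerate(others):
                    sel = sources == k
                    if sel.any():
                        parts.append(self._offspring(self.demes[other], int(sel.sum()), fit_a))
            if seep_name is not None and (sources == -2).any():
                parts.append(self._offspring(self.demes[seep_name], int((sources == -2).sum()), fit_r))
            new[name] = np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]
        for name in r_names:
            new[name] = self._offspring(self.demes[name], cfg.Ne_resident, fit_r)
        for name, H in new.items():
            self.demes[name] = H
        self._mutate()
        self._prune()

    # -- output ---------------------------------------------------------------

    def _sample(self, a_names, r_names):
        cfg = self.cfg
        rng = self.rng
        sampled = []
        deme_order = [d for river in cfg.rivers for d in (f"A_{river}", f"R_{river}")]
        focal_freqs = {}
        for name in deme_order:
            H = self.demes[name]
            n_ind = H.shape[0] // 2
            pick = np.sort(rng.choice(n_ind, size=cfg.samples_per_population, replace=False))
            rows = np.stack([2 * pick, 2 * pick + 1], axis=1).ravel()
            sampled.append(H[rows])
            if self.focal_x >= 0:
                focal_freqs[name] = float(H[:, self.focal_x].mean())
            else:
                focal_freqs[name] = float("nan")
        S = np.concatenate(sampled, axis=0)  # (2*total_ind, n_cols)
        dos = (S[::2].astype(np.int8) + S[1::2].astype(np.int8))  # (ind, cols)
        tot = dos.sum(axis=0, dtype=np.int64)
        seg = (tot > 0) & (tot < 2 * dos.shape[0])
        order = np.argsort(self.positions[seg], kind="mergesort")
        pos = self.positions[seg][order]
        dos = dos[:, seg][:, order].T  # (sites, individuals)
        focal_pos = int(self.positions[self.focal_x]) if self.focal_x >= 0 else -1
        return pos, dos, focal_pos, focal_freqs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _run_planted_window(config, locus, ss, max_retries: int = 5):
    """Run a forward window, re-seeding if a required focal allele is lost."""
    needs_segregation = locus.regime == "BALANCED_ANAD"
    attempt_ss = ss
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(attempt_ss)
        fw = _ForwardWindow(config, locus, rng)
        pos, dos, focal_pos, focal_freqs = fw.run()
        if not needs_segregation:
            return pos, dos, focal_pos, focal_freqs
        a_freqs = [f for d, f in focal_freqs.items() if d.startswith("A_")]
        if any(0.0 < f < 1.0 for f in a_freqs):
            return pos, dos, focal_pos, focal_freqs
        warnings.warn(
            f"window {locus.window_index}: balanced allele lost, re-seeding (attempt {attempt + 1})"
        )
        attempt_ss = np.random.SeedSequence(entropy=attempt_ss.entropy, spawn_key=(997 + attempt,))
    return pos, dos, focal_pos, focal_freqs  # give up; keep the last attempt


def simulate_dataset(config: DemographyConfig, plan: SelectionPlan | None = None) -> SimulatedDataset:
    """Simulate the full genotype dataset, mask, panel and truth table."""
    plan = plan or SelectionPlan([])
    planted = plan.regime_of()
    for idx in planted:
        if not 0 <= idx < config.n_windows:
            raise ValidationError(f"planted window index {idx} outside the grid")
    panel = _build_panel(config)
    master = np.random.SeedSequence(config.seed)
    window_seeds = master.spawn(config.n_windows)

    contigs = list(config.contig_lengths)
    wlen = config.window_length
    per_contig = config.windows_per_contig
    contig_of = np.repeat(np.arange(config.n_chromosomes), per_contig)
    first_window = np.concatenate([[0], np.cumsum(per_contig)[:-1]])
    deme_order = [d for river in config.rivers for d in (f"A_{river}", f"R_{river}")]

    all_contig, all_pos, all_dos = [], [], []
    truth_rows = []
    for widx in range(config.n_windows):
        cidx = int(contig_of[widx])
        chrom = contigs[cidx]
        offset = int(widx - first_window[cidx]) * wlen
        locus = planted.get(widx)
        if locus is None or locus.regime == "NEUTRAL" or locus.s == 0.0:
            pos, dos = _neutral_window(config, window_seeds[widx])
            if locus is not None:
                truth_rows.append(
                    {"window_index": widx, "contig": chrom, "start": offset, "end": offset + wlen,
                     "regime": locus.regime, "s": locus.s, "h": locus.h, "focal_pos": -1,
                     **{f"freq_{d}": float("nan") for d in deme_order}}
                )
        else:
            pos, dos, focal_pos, focal_freqs = _run_planted_window(config, locus, window_seeds[widx])
            truth_rows.append(
                {"window_index": widx, "contig": chrom, "start": offset, "end": offset + wlen,
                 "regime": locus.regime, "s": locus.s, "h": locus.h,
                 "focal_pos": offset + focal_pos if focal_pos >= 0 else -1,
                 **{f"freq_{d}": focal_freqs[d] for d in deme_order}}
            )
        all_contig.append(np.full(len(pos), cidx, dtype=np.int32))
        all_pos.append(pos + offset)
        all_dos.append(dos)

    contig_idx = np.concatenate(all_contig)
    pos = np.concatenate(all_pos)
    dos = np.concatenate(all_dos, axis=0)  # (sites, individuals), alt dosage

    # fold to the globally minor allele, as core_io does at load time
    n_ind = dos.shape[1]
    alt_counts = dos.sum(axis=1, dtype=np.int64)
    flip = alt_counts * 2 > 2 * n_ind  # alt frequency > 0.5
    dos[flip] = 2 - dos[flip]

    ref = np.array(list(_BASES))[pos % 4]
    alt = np.array(list(_BASES))[(pos + 1) % 4]
    sites = pd.DataFrame(
        {"contig": np.array(contigs)[contig_idx], "pos": pos, "ref": ref, "alt": alt}
    )
    G = GenotypeMatrix(
        sample_ids=list(panel.table["sample"]),
        sites=sites,
        calls=np.ascontiguousarray(dos.T),
    )
    mask = [(c, 0, length) for c, length in config.contig_lengths.items()]
    truth_cols = ["window_index", "contig", "start", "end", "regime", "s", "h", "focal_pos"] + [
        f"freq_{d}" for d in deme_order
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SimulatedDataset(
        genotypes=G, mask=mask, panel=panel, truth=truth,
        contig_lengths=config.contig_lengths,
    )


# ---------------------------------------------------------------------------
# genotype-likelihood fixture generator
# ---------------------------------------------------------------------------


def simulate_genotype_likelihoods(
    genotypes: np.ndarray,
    mean_depth: float = 5.0,
    error_rate: float = 0.01,
    seed: int | None = None,
) -> np.ndarray:
    """Linear-scale genotype likelihoods from true genotypes under a
    Poisson-depth, symmetric-error read model.

    ``genotypes``: (n_sites, n_samples) dosages in {0, 1, 2}. Returns an
    array (n_sites, n_samples, 3) of likelihoods of (RR, RA, AA) given the
    simulated read pile-ups; zero-depth sites are uninformative (1, 1, 1).
    """
    from scipy.stats import binom

    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes)
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])
    depth = rng.poisson(mean_depth, size=g.shape)
    k_alt = rng.binomial(depth, p_alt[g])
    gl = np.empty(g.shape + (3,), dtype=float)
    for gg in range(3):
        gl[..., gg] = binom.pmf(k_alt, depth, p_alt[gg])
    gl[depth == 0] = 1.0
    return gl


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def emit_files(dataset: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write VCF + BED mask + panel TSV + truth TSV; deterministic bytes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "synthetic.vcf",
        "mask": out / "callable_mask.bed",
        "panel": out / "panel.tsv",
        "truth": out / "truth.tsv",
    }
    _write_vcf(dataset.genotypes, dataset.contig_lengths, paths["vcf"])
    pd.DataFrame(dataset.mask).to_csv(paths["mask"], sep="\t", index=False, header=False)
    dataset.panel.table.to_csv(paths["panel"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return {k: str(v) for k, v in paths.items()}


def _write_vcf(G: GenotypeMatrix, contig_lengths: dict[str, int], path) -> None:
    n_samples = G.n_samples
    header = ["##fileformat=VCFv4.2", "##source=amtscan-simulate"]
    header += [f"##contig=<ID={c},length={l}>" for c, l in contig_lengths.items()]
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.sample_ids))

    # fixed-width genotype field rendering: 4 bytes per sample ("0/0\t")
    lut = np.frombuffer(b"0/0\t0/1\t1/1\t./.\t", dtype=np.uint32)
    codes = G.calls.T.astype(np.int64)  # (sites, samples)
    codes[codes < 0] = 3
    body = lut[codes]  # uint32 per sample field
    row_bytes = body.tobytes()
    stride = 4 * n_samples

    contig = G.sites["contig"].to_numpy()
    pos = G.sites["pos"].to_numpy()
    ref = G.sites["ref"].to_numpy()
    alt = G.sites["alt"].to_numpy()
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        for i in range(G.n_sites):
            prefix = f"{contig[i]}\t{pos[i] + 1}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t"
            fh.write(prefix.encode() + row_bytes[i * stride : (i + 1) * stride - 1] + b"\n")
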