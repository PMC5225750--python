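"""Synthetic breeding populations and clonally replicated trials.

The generator emulates the structure of a clonal strawberry-style breeding
program: founder haplotypes with linkage disequilibrium decaying over
centimorgan distances, a circular mating design among parents, Mendelian
gene drop with Haldane recombination, and plot-level phenotypes with the
variance partition the trial analysis assumes (additive + family +
clone-within-family genetic effects, bed and subplot nuisance strata,
optional transplant-weight covariate, and a controllable cross-trial
additive correlation for two-trial genotype-by-environment studies).

Meiosis is simulated as diploid: SNP arrays for octoploid crops deliver
disomic dosage calls and every downstream method treats markers as diploid
dosages, so the generator produces data at that same resolution.

Default magnitudes follow the study conditions the package is tested
against: 28 linkage groups totalling ~1700 cM, heritability targets in the
0.03-0.46 narrow-sense / 0.29-0.66 broad-sense range, three clonal
replicates with three beds of eight subplots each, and LD extending over
~10 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix
from .ld import GeneticMap
from .mixed_models import TrialData
from .relationships import PedigreeTable

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_founder_haplotypes",
    "make_circular_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_trials",
]


@dataclass
class SimConfig:
    """All knobs of the generator; every stochastic call derives from ``seed``."""

    n_parents: int = 22
    progeny_per_cross: int = 10
    n_markers: int = 1400
    n_lgs: int = 28
    lg_length_cm: float = 60.0
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    block_cm: float = 10.0         # haplotype-mosaic segment scale (founder LD)
    n_ancestral: int = 4           # ancestral haplotype pool per LG
    n_qtl: int = 100
    h2: float = 0.30               # narrow-sense target (total variance = 1)
    family_frac: float = 0.10      # family variance fraction
    clone_frac: float = 0.10       # clone-within-family fraction
    bed_frac: float = 0.05
    plot_frac: float = 0.05
    n_reps: int = 3
    beds_per_rep: int = 3
    plots_per_bed: int = 8
    type_b: float = 1.0            # cross-trial additive correlation target
    trial_overlap_frac: float = 0.15   # genotypes shared between paired trials
    covariate_beta: float = 0.0    # transplant-weight effect (per unit weight)
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.h2 + self.family_frac + self.clone_frac
                 + self.bed_frac + self.plot_frac)
        if total > 1.0 + 1e-9:
            raise ValueError("variance fractions sum above 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.type_b <= 1.0:
            raise ValueError("type_b must be in (0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("more QTL than markers")

    @property
    def residual_frac(self) -> float:
        return 1.0 - (self.h2 + self.family_frac + self.clone_frac
                      + self.bed_frac + self.plot_frac)


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    gmap: GeneticMap
    pedigree: PedigreeTable
    markers: MarkerMatrix          # all pedigree members (founders + progeny)
    trial_data: TrialData
    truth: dict = field(default_factory=dict)

    @property
    def genotyped_ids(self) -> list[str]:
        return self.truth["genotype_ids"]

    def trial_markers(self) -> MarkerMatrix:
        return self.markers.subset_individuals(self.genotyped_ids)


def _random_map(cfg: SimConfig, rng: np.random.Generator) -> GeneticMap:
    per_lg = np.full(cfg.n_lgs, cfg.n_markers // cfg.n_lgs)
    per_lg[: cfg.n_markers % cfg.n_lgs] += 1
    rows = []
    m_idx = 0
    for g in range(cfg.n_lgs):
        pos = np.sort(rng.uniform(0.0, cfg.lg_length_cm, size=per_lg[g]))
        for x in pos:
            rows.append((f"M{m_idx:05d}", f"LG{g + 1:02d}", float(x)))
            m_idx += 1
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "lg", "cm"]))


def simulate_founder_haplotypes(cfg: SimConfig
                                ) -> tuple[np.ndarray, GeneticMap]:
    """Founder haplotypes (n_parents x 2 x n_markers, alleles 0/1) plus a map.

    Each haplotype is a mosaic of a small pool of ancestral haplotypes; the
    mosaic switches between pool members as an exponential process with
    scale ``block_cm``, so marker pairs closer than a segment tend to share
    an ancestral origin and are in LD, decaying with cM distance.
    ``block_cm <= 0`` draws every marker independently (no LD).
    """
    if cfg.n_markers <= 0 or cfg.n_parents <= 0:
        raise ValueError("need at least one marker and one founder")
    rng = np.random.default_rng(cfg.seed)
    gmap = _random_map(cfg, rng)
    lo, hi = cfg.founder_freq_range
    freqs = rng.uniform(lo, hi, size=cfg.n_markers)
    haps = np.zeros((cfg.n_parents, 2, cfg.n_markers), dtype=np.int8)
    marker_order = {mk: j for j, mk in enumerate(gmap.df["marker"])}
    for lg in gmap.linkage_groups:
        sub = gmap.markers_on(lg)
        cols = np.array([marker_order[mk] for mk in sub["marker"]])
        pos = sub["cm"].to_numpy(dtype=float)
        p_lg = freqs[cols]
        if cfg.block_cm <= 0:
            draw = rng.random((cfg.n_parents, 2, len(cols))) < p_lg
            haps[:, :, cols] = draw.astype(np.int8)
            continue
        pool = (rng.random((cfg.n_ancestral, len(cols))) < p_lg).astype(np.int8)
        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-gaps / cfg.block_cm)
        for f in range(cfg.n_parents):
            for h in range(2):
                state = np.empty(len(cols), dtype=np.int64)
                state[0] = rng.integers(cfg.n_ancestral)
                switches = rng.random(len(gaps)) < p_switch
                cur = state[0]
                for j, sw in enumerate(switches, start=1):
                    if sw:
                        cur = rng.integers(cfg.n_ancestral)
                    state[j] = cur
                haps[f, h, cols] = pool[state, np.arange(len(cols))]
    return haps, gmap


def make_circular_pedigree(parent_ids: list[str], progeny_per_cross: int = 10,
                           extra_crosses: list[tuple[str, str]] | None = None,
                           ) -> PedigreeTable:
    """Circular mating design: cross parent i with parent i+1, wrapping round.

    Produces one family per parent (plus any extra crosses appended);
    progeny are named ``<sire>x<dam>_<k>``.
    """
    parent_ids = [str(p) for p in parent_ids]
    if len(parent_ids) < 3:
        raise ValueError("circular mating needs at least 3 parents")
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("duplicate parent ids")
    records: list[tuple[str, str | None, str | None]] = [
        (p, None, None) for p in parent_ids]
    crosses = [(parent_ids[i], parent_ids[(i + 1) % len(parent_ids)])
               for i in range(len(parent_ids))]
    crosses += [(str(a), str(b)) for a, b in (extra_crosses or [])]
    for sire, dam in crosses:
        for k in range(progeny_per_cross):
            records.append((f"{sire}x{dam}_{k}", sire, dam))
    return PedigreeTable(records)


def _meiosis(parent_haps: np.ndarray, gmap: GeneticMap,
             marker_order: dict[str, int], rng: np.random.Generator
             ) -> np.ndarray:
    """One gamete: Haldane crossover process along each linkage group."""
    gamete = np.empty(parent_haps.shape[1], dtype=np.int8)
    for lg in gmap.linkage_groups:
        sub = gmap.markers_on(lg)
        cols = np.array([marker_order[mk] for mk in sub["marker"]])
        d = np.diff(sub["cm"].to_numpy(dtype=float))
        c = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        switches = rng.random(len(d)) < c
        strand = np.empty(len(cols), dtype=np.int64)
        strand[0] = rng.integers(2)
        if len(d):
            strand[1:] = (strand[0] + np.cumsum(switches)) % 2
        gamete[cols] = parent_haps[strand, cols]
    return gamete


def gene_drop(ped: PedigreeTable, founder_haps: np.ndarray, gmap: GeneticMap,
              seed: int = 0) -> MarkerMatrix:
    """Drop founder haplotypes through the pedigree; returns dosages for all
    pedigree members.

    Founders (records with both parents unknown) consume ``founder_haps``
    rows in pedigree order; offspring receive one recombinant gamete from
    each parent (Haldane model: crossover probability between adjacent
    markers ``c = 0.5 (1 - exp(-2 d / 100))`` for ``d`` cM).
    """
    n_markers = founder_haps.shape[2]
    if len(gmap.df) != n_markers:
        raise ValueError("map size does not match founder haplotypes")
    rng = np.random.default_rng(seed)
    marker_order = {mk: j for j, mk in enumerate(gmap.df["marker"])}
    haps: dict[str, np.ndarray] = {}
    founder_i = 0
    for rid, sire, dam in ped.records:
        if sire is None and dam is None:
            if founder_i >= founder_haps.shape[0]:
                raise ValueError("more founders in pedigree than haplotypes")
            haps[rid] = founder_haps[founder_i].copy()
            founder_i += 1
        else:
            pair = np.empty((2, n_markers), dtype=np.int8)
            for slot, parent in enumerate((sire, dam)):
                if parent is None:
                    # unknown single parent: draw an unrelated founder gamete
                    freq = founder_haps.reshape(-1, n_markers).mean(axis=0)
                    pair[slot] = (rng.random(n_markers) < freq).astype(np.int8)
                else:
                    pair[slot] = _meiosis(haps[parent], gmap, marker_order, rng)
            haps[rid] = pair
    ids = ped.ids
    dosages = np.array([haps[i].sum(axis=0) for i in ids], dtype=float)
    return MarkerMatrix(ids, list(gmap.df["marker"]), dosages)


def _scaled(values: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a vector to exactly the target variance."""
    v = values - values.mean()
    sd = v.std()
    if target_var == 0.0 or sd == 0.0:
        return np.zeros_like(v)
    return v * (np.sqrt(target_var) / sd)


def simulate_phenotypes(markers: MarkerMatrix, ped: PedigreeTable,
                        cfg: SimConfig, trials: tuple[str, ...] = ("T1",),
                        seed: int | None = None
                        ) -> tuple[TrialData, dict]:
    """Plot-level phenotypes for one or two trials, plus a truth record.

    Total phenotypic variance is 1 by construction. Additive values come
    from ``n_qtl`` marker effects rescaled to the target additive variance;
    in two-trial mode each trial's additive value is
    ``sqrt(r_B) a0 + sqrt(1 - r_B) d_t`` with trial-specific marker-based
    deviations ``d_t``, so the cross-trial additive correlation equals the
    ``type_b`` target. Family and clone deviations are shared across trials.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    geno_ids = [rid for rid, s, d in ped.records if s is not None or d is not None]
    if not geno_ids:
        raise ValueError("pedigree has no progeny to phenotype")
    gm = markers.subset_individuals(geno_ids)
    X = gm.dosages
    p = X.mean(axis=0) / 2.0
    Xc = X - 2.0 * p

    qtl = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
    alpha = rng.normal(size=cfg.n_qtl)
    a0 = _scaled(Xc[:, qtl] @ alpha, cfg.h2)

    fam_map = ped.families()
    fams = sorted({fam_map[g] for g in geno_ids})
    fam_eff = dict(zip(fams, _scaled(rng.normal(size=len(fams)),
                                     cfg.family_frac)))
    clone_eff = _scaled(rng.normal(size=len(geno_ids)), cfg.clone_frac)

    additive: dict[str, np.ndarray] = {}
    if len(trials) == 1:
        additive[trials[0]] = a0
    else:
        for t in trials:
            alpha_t = rng.normal(size=cfg.n_qtl)
            qtl_t = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
            d_t = _scaled(Xc[:, qtl_t] @ alpha_t, cfg.h2)
            additive[t] = np.sqrt(cfg.type_b) * a0 + np.sqrt(1 - cfg.type_b) * d_t

    n_g = len(geno_ids)
    # paired trials share a fraction of genotypes (common checks); the rest
    # split between trials and connect only through relatedness
    membership: dict[str, np.ndarray] = {}
    if len(trials) == 1:
        membership[trials[0]] = np.arange(n_g)
    else:
        perm_g = rng.permutation(n_g)
        n_shared = int(round(cfg.trial_overlap_frac * n_g))
        shared = perm_g[:n_shared]
        rest = perm_g[n_shared:]
        halves = np.array_split(rest, len(trials))
        for t, own in zip(trials, halves):
            membership[t] = np.sort(np.concatenate([shared, own]))

    rows = []
    sigma_b = np.sqrt(cfg.bed_frac)
    sigma_p = np.sqrt(cfg.plot_frac)
    sigma_e = np.sqrt(cfg.residual_frac)
    for t in trials:
        a_t = additive[t]
        members = membership[t]
        for rep in range(1, cfg.n_reps + 1):
            perm = members[rng.permutation(len(members))]
            bed_effects = rng.normal(0.0, sigma_b, size=cfg.beds_per_rep)
            plot_effects = rng.normal(
                0.0, sigma_p, size=(cfg.beds_per_rep, cfg.plots_per_bed))
            for slot, gi in enumerate(perm):
                bed = slot % cfg.beds_per_rep
                plot = (slot // cfg.beds_per_rep) % cfg.plots_per_bed
                g = geno_ids[gi]
                genetic = a_t[gi] + fam_eff[fam_map[g]] + clone_eff[gi]
                w = rng.normal()
                yv = (genetic + bed_effects[bed] + plot_effects[bed, plot]
                      + rng.normal(0.0, sigma_e) + cfg.covariate_beta * w)
                rows.append((t, f"R{rep}", f"B{bed + 1}", f"P{plot + 1}",
                             g, fam_map[g], w, yv))
    df = pd.DataFrame(rows, columns=["trial", "rep", "bed", "plot",
                                     "genotype", "family", "weight", "trait"])
    truth = {
        "genotype_ids": geno_ids,
        "trial_members": {t: [geno_ids[i] for i in membership[t]]
                          for t in trials},
        "qtl_indices": qtl.tolist(),
        "additive": {t: pd.Series(additive[t], index=geno_ids)
                     for t in trials},
        "family_effects": fam_eff,
        "clone_effects": pd.Series(clone_eff, index=geno_ids),
        "total_genetic": {
            t: pd.Series(additive[t]
                         + np.array([fam_eff[fam_map[g]] for g in geno_ids])
                         + clone_eff, index=geno_ids) for t in trials},
        "components": {"additive": cfg.h2, "family": cfg.family_frac,
                       "clone": cfg.clone_frac, "bed": cfg.bed_frac,
                       "plot": cfg.plot_frac, "residual": cfg.residual_frac},
        "type_b": cfg.type_b,
    }
    return TrialData(df), truth


def simulate_trials(cfg: SimConfig, trials: tuple[str, ...] = ("T1",)
                    ) -> SimBundle:
    """Full study simulation: founders -> circular pedigree -> gene drop ->
    phenotypes. All randomness derives from ``cfg.seed``."""
    haps, gmap = simulate_founder_haplotypes(cfg)
    parents = [f"F{i:03d}" for i in range(cfg.n_parents)]
    ped = make_circular_pedigree(parents, cfg.progeny_per_cross)
    markers = gene_drop(ped, haps, gmap, seed=cfg.seed + 7)
    trial_data, truth = simulate_phenotypes(markers, ped, cfg, trials=trials,
                                            seed=cfg.seed + 13)
    return SimBundle(config=cfg, gmap=gmap, pedigree=ped, markers=markers,
                     trial_data=trial_data, truth=truth)


def scaled_config(cfg: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **overrides)
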