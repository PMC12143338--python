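"""Seeded simulator for multi-lineage immune single-cell datasets.

The generator produces a :class:`~immunogate.bundle.CountBundle`, a
:class:`GroundTruth` table and a V(D)J contig table with known structure so
every pipeline stage is testable without external data. The statistical model:

* per-gene baseline expression is log-normal; population marker genes are
  up-regulated by a configured fold change;
* T-lineage cells carry a latent differentiation coordinate ``d`` in [0, 1]
  (naive -> effector). Program genes respond to ``d``: lymph-node-homing /
  naive genes decline, S100A and memory genes rise, GZMM declines, GZMK peaks
  at intermediate ``d``, and GZMB/GZMH rise steeply toward the effector pole;
* UMI counts are negative binomial (gamma-Poisson) around library-size-scaled
  relative expression; Poisson is the infinite-dispersion limit;
* sequencing reads per cell are the UMI total plus a negative-binomial number
  of duplicate reads (sum of per-molecule shifted-geometric draws), so reads
  >= UMIs by construction and saturation varies smoothly across cells;
* a deterministic ``round(rate * n)`` number of cells become doublets by
  adding the counts of a second parent sampled from a different population;
* T cells receive clonotypes: a fixed number of clones per subject with
  power-law sizes, a configurable fraction drawing their CDR3 from a shared
  pool (public clones).

All randomness flows from a single ``numpy`` Generator seeded by the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .bundle import CountBundle
from .exceptions import ConfigError
from .tcr import ContigRecord

AA_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = list("ACGT")

# -- gradient programs ----------------------------------------------------
# law: multiplicative factor on mean expression as a function of latent d.
#   up     1 + (f-1) * d             (S100A/memory program)
#   up2    1 + (f-1) * d^2           (effector granzymes: late switch-on)
#   down   1 + (f-1) * (1-d)         (naive / lymph-node homing program)
#   down2  1 + (f-1) * (1-d)^2       (GZMM: early switch-off)
#   peak   1 + (f-1) * 4 d (1-d)     (GZMK: central-memory peak)

GRADIENT_LAWS = ("up", "up2", "down", "down2", "peak")


def gradient_factor(law: str, fold: float, d: np.ndarray) -> np.ndarray:
    if law == "up":
        shape = d
    elif law == "up2":
        shape = d**2
    elif law == "down":
        shape = 1.0 - d
    elif law == "down2":
        shape = (1.0 - d) ** 2
    elif law == "peak":
        shape = 4.0 * d * (1.0 - d)
    else:
        raise ConfigError(f"unknown gradient law {law!r}")
    return 1.0 + (fold - 1.0) * shape


def default_gradient_program() -> dict[str, tuple[str, float]]:
    """Gene -> (law, fold) for the naive->effector differentiation gradient."""
    prog: dict[str, tuple[str, float]] = {
        # naive / lymph-node homing: decline with differentiation
        "CCR7": ("down", 6.0),
        "SELL": ("down", 6.0),
        "LEF1": ("down", 5.0),
        "TCF7": ("down", 4.0),
        "KLF2": ("down", 3.0),
        "NSA2": ("down", 3.0),
        "GYPC": ("down", 3.0),
        # granzyme switch
        "GZMM": ("down2", 5.0),
        "GZMK": ("peak", 6.0),
        "GZMA": ("up2", 3.0),
        "GZMB": ("up2", 6.0),
        "GZMH": ("up2", 6.0),
        "PRF1": ("up2", 4.0),
        # S100A / memory program: rise with differentiation
        "S100A4": ("up", 6.0),
        "S100A6": ("up", 6.0),
        "S100A10": ("up", 5.0),
        "S100A11": ("up", 5.0),
        "ANXA1": ("up", 3.0),
        "ANXA2": ("up", 3.0),
        "CRIP1": ("up", 3.0),
        "ITGB1": ("up", 3.0),
        "ID2": ("up", 3.0),
        "CCL5": ("up", 4.0),
    }
    for i in range(1, 56):
        prog[f"MEMUP{i:02d}"] = ("up", 4.0)
        prog[f"MEMDN{i:02d}"] = ("down", 4.0)
    for i in range(1, 9):
        prog[f"MEMPK{i:02d}"] = ("peak", 4.0)
    return prog


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population."""

    name: str
    n_cells: int
    lineage: str  # coarse lineage label (T_NK, B, Myeloid, Erythroid, ...)
    markers: dict[str, float] = field(default_factory=dict)  # gene -> fold
    t_lineage: bool = False  # carries latent d and the gradient program
    d_range: tuple[float, float] | None = None
    clonotyped: bool = False
    contig_loci: tuple[str, str] = ("TRB", "TRA")  # (primary, secondary) chains
    adt_positive: tuple[str, ...] = ()
    tissue_weights: dict[str, float] | None = None


@dataclass
class SimulationConfig:
    """Everything the generator needs; identical seed => identical outputs."""

    populations: list[PopulationSpec]
    n_genes: int = 5000
    gradient: dict[str, tuple[str, float]] = field(
        default_factory=default_gradient_program
    )
    base_log_mean: float = 0.0  # filler-gene log-normal baseline
    base_log_sd: float = 1.5
    program_log_mean: float = 1.2  # gradient-program genes: broadly expressed tail
    program_log_sd: float = 0.4
    marker_log_mean: float = -1.0  # lineage markers: near-off outside their pop
    marker_log_sd: float = 0.4
    dispersion: float = 10.0  # NB size theta; var = mu + mu^2/theta
    library_log_mean: float = math.log(6000.0)
    library_log_sd: float = 0.25
    reads_per_umi_p: float = 0.35  # shifted-geometric success prob per molecule
    doublet_rate: float = 0.05
    n_subjects: int = 4
    n_lanes: int = 2
    clones_per_subject: int = 40
    clone_power: float = 1.5
    public_clone_fraction: float = 0.10
    adt_tags: tuple[str, ...] = ("CD3", "CD20", "CD16")
    adt_background_mean: float = 5.0
    adt_positive_mean: float = 60.0
    adt_dispersion: float = 5.0
    adt_reads_p: float = 0.15
    with_adt: bool = True
    tissues: tuple[str, ...] = ("PBMC", "Spleen", "LymphNode", "Liver", "Lung")
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("empty population list")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise ConfigError("doublet_rate must lie in [0, 0.5)")
        if not (0.0 < self.reads_per_umi_p <= 1.0):
            raise ConfigError("reads_per_umi_p must lie in (0, 1]")
        if not (0.0 <= self.public_clone_fraction <= 1.0):
            raise ConfigError("public_clone_fraction must lie in [0, 1]")
        for p in self.populations:
            if p.t_lineage and p.d_range is None:
                raise ConfigError(f"population {p.name}: T lineage without d_range")


@dataclass
class GroundTruth:
    """Per-cell and per-gene generating truth."""

    cells: pd.DataFrame  # population, lineage, d, is_doublet, parent_populations,
    #                      partner_index, clonotype_id, subject, lane, tissue
    genes: pd.DataFrame  # gene, role, law, fold


_T_CD3 = {"CD3D": 80.0, "CD3E": 70.0, "CD3G": 50.0, "TRAC": 60.0}

# Registry guard genes kept at baseline in every simulation so module files
# apply unchanged (erythroid/platelet guards, mature-B programs).
_REGISTRY_BASELINE = [
    "HBB", "HBA1", "ALAS2", "PPBP", "PF4", "ITGA2B",
    "AHNAK", "CD1C", "SOX5", "PLAC8", "CR2", "LY86", "CD44",
    "TCL1A", "FCER2", "CXCR4",
]


def coarse_default_config(seed: int = 0, n_per_pop: int = 500) -> SimulationConfig:
    """Six-population dataset: three T stages along the differentiation
    gradient, CD16+ NK cells, B cells and myeloid cells."""
    pops = [
        PopulationSpec(
            "T_naive", n_per_pop, "T_NK", dict(_T_CD3), t_lineage=True,
            d_range=(0.02, 0.25), clonotyped=True, adt_positive=("CD3",),
            tissue_weights={"PBMC": 0.3, "LymphNode": 0.45, "Spleen": 0.2,
                            "Liver": 0.03, "Lung": 0.02},
        ),
        PopulationSpec(
            "T_cm", n_per_pop, "T_NK", dict(_T_CD3), t_lineage=True,
            d_range=(0.35, 0.65), clonotyped=True, adt_positive=("CD3",),
            tissue_weights={"PBMC": 0.3, "LymphNode": 0.3, "Spleen": 0.25,
                            "Liver": 0.1, "Lung": 0.05},
        ),
        PopulationSpec(
            "T_em", n_per_pop, "T_NK", dict(_T_CD3), t_lineage=True,
            d_range=(0.75, 0.98), clonotyped=True, adt_positive=("CD3",),
            tissue_weights={"PBMC": 0.35, "LymphNode": 0.1, "Spleen": 0.2,
                            "Liver": 0.2, "Lung": 0.15},
        ),
        PopulationSpec(
            "NK", n_per_pop, "T_NK",
            {"NKG7": 80.0, "GNLY": 80.0, "FCGR3": 50.0, "KLRD1": 40.0,
             "GZMA": 8.0, "GZMB": 6.0, "GZMH": 6.0},
            adt_positive=("CD16",),
            tissue_weights={"PBMC": 0.5, "LymphNode": 0.05, "Spleen": 0.15,
                            "Liver": 0.25, "Lung": 0.05},
        ),
        PopulationSpec(
            "B", n_per_pop, "B",
            {"MS4A1": 80.0, "CD79A": 70.0, "CD79B": 60.0, "CD19": 40.0},
            adt_positive=("CD20",),
            tissue_weights={"PBMC": 0.3, "LymphNode": 0.4, "Spleen": 0.25,
                            "Liver": 0.03, "Lung": 0.02},
        ),
        PopulationSpec(
            "Myeloid", n_per_pop, "Myeloid",
            {"LYZ": 100.0, "VCAN": 60.0, "CD68": 50.0, "CD14": 40.0},
            tissue_weights={"PBMC": 0.4, "LymphNode": 0.05, "Spleen": 0.15,
                            "Liver": 0.15, "Lung": 0.25},
        ),
    ]
    return SimulationConfig(populations=pops, seed=seed)


_SORTED_D = {
    "TN": (0.02, 0.20),
    "TCM_TM": (0.35, 0.65),
    "TEM": (0.80, 0.98),
    "GD": (0.45, 0.90),
}


def sorted_reference_config(seed: int = 0, n_per_pop: int = 500) -> SimulationConfig:
    """Seven sorted peripheral T cell populations (CD4/CD8 naive, central/
    transitional memory, effector memory, plus gamma-delta) with branch-
    specific marker programs layered on the shared differentiation gradient."""
    cd8_branch = {"CD8A": 25.0, "CD8B": 20.0}
    cd8_branch.update({f"CTX{i:02d}": 12.0 for i in range(1, 16)})
    cd4_branch = {"CD4": 4.0}
    cd4_branch.update({f"HLP{i:02d}": 12.0 for i in range(1, 16)})
    gd_branch = {"TRDC": 30.0, "TRGC1": 20.0}
    gd_branch.update({f"GDT{i:02d}": 12.0 for i in range(1, 11)})

    def pop(name, stage, branch, loci=("TRB", "TRA")):
        markers = dict(_T_CD3)
        markers.update(branch)
        return PopulationSpec(
            name, n_per_pop, "T_NK", markers, t_lineage=True,
            d_range=_SORTED_D[stage], clonotyped=True, contig_loci=loci,
            adt_positive=("CD3",),
            tissue_weights={"PBMC": 1.0},
        )

    pops = [
        pop("CD4_TN", "TN", cd4_branch),
        pop("CD8_TN", "TN", cd8_branch),
        pop("CD4_TCM_TM", "TCM_TM", cd4_branch),
        pop("CD8_TCM_TM", "TCM_TM", cd8_branch),
        pop("CD4_TEM", "TEM", cd4_branch),
        pop("CD8_TEM", "TEM", cd8_branch),
        pop("GD", "GD", gd_branch, loci=("TRD", "TRG")),
    ]
    return SimulationConfig(populations=pops, with_adt=False, seed=seed)


def _build_gene_list(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Ordered gene list: program/marker genes first, then filler.

    The special-gene list keeps a deterministic order (gradient, then
    population markers, then registry guards) so that per-gene baseline draws
    consume the random stream identically for a given config.
    """
    special: list[str] = []
    seen = set()
    for g in list(config.gradient):
        if g not in seen:
            special.append(g)
            seen.add(g)
    for p in config.populations:
        for g in p.markers:
            if g not in seen:
                special.append(g)
                seen.add(g)
    for g in _REGISTRY_BASELINE:
        if g not in seen:
            special.append(g)
            seen.add(g)
    n_filler = config.n_genes - len(special)
    if n_filler < 0:
        raise ConfigError("n_genes smaller than the number of program genes")
    genes = special + [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    return genes, special


def _random_cdr3(rng: np.random.Generator, prefix: str = "CASS", length: int = 8):
    body = "".join(rng.choice(AA_ALPHABET, size=length))
    return f"{prefix}{body}F"


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NT_ALPHABET, size=length))


_LOCUS_SEGMENTS = {
    "TRA": ("TRAV", 20, "TRAJ", 30, "TRAC"),
    "TRB": ("TRBV", 20, "TRBJ", 12, "TRBC1"),
    "TRG": ("TRGV", 8, "TRGJ", 4, "TRGC1"),
    "TRD": ("TRDV", 3, "TRDJ", 4, "TRDC"),
}

_CDR3_PREFIX = {"TRA": "CAV", "TRB": "CASS", "TRG": "CATW", "TRD": "CALG"}


def _make_contig(rng, barcode, subject, locus, cdr3, umis) -> ContigRecord:
    vpref, nv, jpref, nj, cgene = _LOCUS_SEGMENTS[locus]
    return ContigRecord(
        barcode=barcode,
        subject_id=subject,
        chain=locus,
        v_gene=f"{vpref}{int(rng.integers(1, nv + 1))}",
        d_gene=None,
        j_gene=f"{jpref}{int(rng.integers(1, nj + 1))}",
        c_gene=cgene,
        cdr3_aa=cdr3,
        cdr3_nt=_random_nt(rng, 3 * len(cdr3)),
        full_length=True,
        productive=True,
        umis=int(umis),
    )


def simulate_immune_dataset(
    config: SimulationConfig,
) -> tuple[CountBundle, GroundTruth, list[ContigRecord]]:
    """Generate (bundle, ground truth, contig records) from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes, special = _build_gene_list(config)
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    # per-gene baselines in three tiers: broadly expressed gradient-program
    # genes, near-off lineage markers (large fold in their own population),
    # and log-normal filler
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, n_genes)
    gradient_genes = set(config.gradient)
    for g in special:
        if g in gradient_genes:
            base[gene_index[g]] = rng.lognormal(
                config.program_log_mean, config.program_log_sd
            )
        else:
            base[gene_index[g]] = rng.lognormal(
                config.marker_log_mean, config.marker_log_sd
            )

    # -- per-cell truth ---------------------------------------------------
    pops, d_vals = [], []
    for p in config.populations:
        pops.extend([p.name] * p.n_cells)
        if p.t_lineage:
            lo, hi = p.d_range
            d_vals.append(rng.uniform(lo, hi, p.n_cells))
        else:
            d_vals.append(np.full(p.n_cells, np.nan))
    d = np.concatenate(d_vals)
    pop_arr = np.array(pops)
    n_cells = len(pop_arr)
    pop_by_name = {p.name: p for p in config.populations}
    lineage = np.array([pop_by_name[p].lineage for p in pop_arr])

    subjects = np.array(
        [f"S{int(i) + 1}" for i in rng.integers(0, config.n_subjects, n_cells)]
    )
    lanes = np.array(
        [f"L{int(i) + 1}" for i in rng.integers(0, config.n_lanes, n_cells)]
    )
    tissues = np.empty(n_cells, dtype=object)
    for p in config.populations:
        mask = pop_arr == p.name
        w = p.tissue_weights or {t: 1.0 for t in config.tissues}
        names = list(w)
        probs = np.array([w[t] for t in names], dtype=float)
        probs /= probs.sum()
        tissues[mask] = rng.choice(names, size=mask.sum(), p=probs)

    # -- expression means --------------------------------------------------
    factors = np.ones((n_cells, n_genes))
    for p in config.populations:
        rows = np.flatnonzero(pop_arr == p.name)
        for g, fold in p.markers.items():
            factors[rows, gene_index[g]] *= fold
    t_rows = np.flatnonzero(~np.isnan(d))
    if len(t_rows):
        for g, (law, fold) in config.gradient.items():
            factors[t_rows, gene_index[g]] *= gradient_factor(law, fold, d[t_rows])

    rel = factors * base[None, :]
    rel /= rel.sum(axis=1, keepdims=True)
    library = rng.lognormal(config.library_log_mean, config.library_log_sd, n_cells)
    mu = rel * library[:, None]
    lam = rng.gamma(config.dispersion, mu / config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    # -- ADT ---------------------------------------------------------------
    adt = None
    if config.with_adt and config.adt_tags:
        tags = list(config.adt_tags)
        adt_mu = np.full((n_cells, len(tags)), config.adt_background_mean)
        for p in config.populations:
            rows = np.flatnonzero(pop_arr == p.name)
            for t in p.adt_positive:
                adt_mu[rows, tags.index(t)] = config.adt_positive_mean
        lane_factor = 1.0 + 0.25 * np.array([int(l[1:]) - 1 for l in lanes])
        adt_mu = adt_mu * lane_factor[:, None]
        adt_lam = rng.gamma(config.adt_dispersion, adt_mu / config.adt_dispersion)
        adt = rng.poisson(adt_lam).astype(np.int64)

    # -- doublets ----------------------------------------------------------
    n_doublets = int(round(config.doublet_rate * n_cells))
    is_doublet = np.zeros(n_cells, dtype=bool)
    partner_index = np.full(n_cells, -1)
    parent_pops = np.array([""] * n_cells, dtype=object)
    if n_doublets:
        hosts = rng.choice(n_cells, size=n_doublets, replace=False)
        host_set = set(hosts.tolist())
        for h in hosts:
            candidates = np.flatnonzero(
                (pop_arr != pop_arr[h])
                & ~np.isin(np.arange(n_cells), list(host_set))
            )
            partner = int(rng.choice(candidates))
            counts[h] += counts[partner]
            if adt is not None:
                adt[h] += adt[partner]
            is_doublet[h] = True
            partner_index[h] = partner
            parent_pops[h] = f"{pop_arr[h]}+{pop_arr[partner]}"

    # -- reads (after doublet merging, so saturation stays well defined) ----
    umis = counts.sum(axis=1)
    dup = rng.negative_binomial(np.maximum(umis, 1), config.reads_per_umi_p)
    reads = umis + np.where(umis > 0, dup, 0)
    adt_reads = None
    if adt is not None:
        adt_umis = adt.sum(axis=1)
        adt_dup = rng.negative_binomial(np.maximum(adt_umis, 1), config.adt_reads_p)
        adt_reads = adt_umis + np.where(adt_umis > 0, adt_dup, 0)

    # -- clonotypes ---------------------------------------------------------
    clonotype_id = np.array([None] * n_cells, dtype=object)
    contigs: list[ContigRecord] = []
    clo_pops = {p.name for p in config.populations if p.clonotyped}
    if clo_pops and config.clones_per_subject > 0:
        eligible = np.flatnonzero(np.isin(pop_arr, list(clo_pops)) & ~is_doublet)
        used_cdr3: set[str] = set()

        def fresh_cdr3(prefix: str) -> str:
            while True:
                c = _random_cdr3(rng, prefix)
                if c not in used_cdr3:
                    used_cdr3.add(c)
                    return c

        n_public_pool = max(
            1, int(math.ceil(config.public_clone_fraction * config.clones_per_subject))
        )
        public_pool = {
            locus: [fresh_cdr3(_CDR3_PREFIX[locus]) for _ in range(n_public_pool)]
            for locus in ("TRB", "TRD")
        }

        clone_counter = 0
        for s in sorted(set(subjects[eligible])):
            cells_s = eligible[subjects[eligible] == s]
            rng.shuffle(cells_s)
            k = min(config.clones_per_subject, len(cells_s))
            if k == 0:
                continue
            weights = (np.arange(1, k + 1) ** -config.clone_power).astype(float)
            weights /= weights.sum()
            extra = rng.multinomial(len(cells_s) - k, weights)
            sizes = 1 + extra
            # public clones draw their primary CDR3 from the shared pool
            n_public = int(round(config.public_clone_fraction * k))
            public_ids = set(
                rng.choice(k, size=min(n_public, n_public_pool), replace=False)
            )
            start = 0
            for ci in range(k):
                members = cells_s[start : start + sizes[ci]]
                start += sizes[ci]
                clone_counter += 1
                cid = f"clone{clone_counter:05d}"
                clonotype_id[members] = cid
                locus1, locus2 = pop_by_name[pop_arr[members[0]]].contig_loci
                if ci in public_ids:
                    cdr3_1 = public_pool[locus1][
                        int(rng.integers(0, n_public_pool))
                    ]
                else:
                    cdr3_1 = fresh_cdr3(_CDR3_PREFIX[locus1])
                cdr3_2 = fresh_cdr3(_CDR3_PREFIX[locus2])
                for cell in members:
                    bc = f"cell{cell:05d}"
                    contigs.append(
                        _make_contig(
                            rng, bc, s, locus1, cdr3_1, rng.integers(2, 21)
                        )
                    )
                    contigs.append(
                        _make_contig(
                            rng, bc, s, locus2, cdr3_2, rng.integers(2, 21)
                        )
                    )

    # -- assemble -----------------------------------------------------------
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "subject_id": subjects,
            "tissue": tissues,
            "lane": lanes,
        }
    )
    bundle = CountBundle(
        cell_ids=cell_ids,
        gene_ids=genes,
        rna_counts=sparse.csr_matrix(counts),
        rna_reads_per_cell=reads,
        meta=meta,
        adt_ids=list(config.adt_tags) if adt is not None else None,
        adt_counts=adt,
        adt_reads_per_cell=adt_reads,
    )

    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "population": pop_arr,
            "lineage": lineage,
            "d": d,
            "is_doublet": is_doublet,
            "parent_populations": parent_pops,
            "partner_index": partner_index,
            "clonotype_id": clonotype_id,
            "subject_id": subjects,
            "lane": lanes,
            "tissue": tissues,
        }
    )
    gene_rows = []
    for g, (law, fold) in config.gradient.items():
        gene_rows.append({"gene": g, "role": "gradient", "law": law, "fold": fold})
    for p in config.populations:
        for g, fold in p.markers.items():
            gene_rows.append(
                {"gene": g, "role": f"marker:{p.name}", "law": "flat", "fold": fold}
            )
    truth = GroundTruth(cells=truth_cells, genes=pd.DataFrame(gene_rows))
    return bundle, truth, contigs
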