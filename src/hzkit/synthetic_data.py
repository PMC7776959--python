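"""Synthetic hybrid-zone and transplant data generators.

Generates genotypes for parental and admixed classes, ancestry clines
along a transect, ancestry-correlated leaf morphometry, and transplant
outcome tables with habitat x phenotype structure — everything the
downstream analysis stages consume, with known truth, from a single
seed. All draws are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .cline import cline_model
from .hybrid_classes import CLASS_Q, CLASSES, ORIGIN_WEIGHTS
from .io_core import GenotypeMatrix, MorphTable, SampleFrame, TransplantTable


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DivergenceConfig:
    """Distribution of per-locus parental allele-frequency pairs.

    ``kind="beta"`` draws f1 ~ Beta(a, b) and f2 ~ Beta(b, a);
    ``kind="fixed"`` uses f1 = 0.5 + d/2, f2 = 0.5 - d/2 at every locus.
    """

    kind: str = "beta"
    a: float = 8.0
    b: float = 2.0
    differential: float = 0.6

    def draw(self, rng: np.random.Generator, n_loci: int
             ) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "beta":
            f1 = rng.beta(self.a, self.b, n_loci)
            f2 = rng.beta(self.b, self.a, n_loci)
        elif self.kind == "fixed":
            d = self.differential
            f1 = np.full(n_loci, 0.5 + d / 2)
            f2 = np.full(n_loci, 0.5 - d / 2)
        else:
            raise ConfigurationError(f"unknown divergence kind {self.kind!r}")
        return np.clip(f1, 1e-4, 1 - 1e-4), np.clip(f2, 1e-4, 1 - 1e-4)


@dataclass
class ClineConfig:
    """True tanh cline and transect geometry (meters)."""

    center: float = 0.0
    width: float = 100.0
    p_left: float = 0.02
    p_right: float = 0.98
    span: tuple[float, float] = (-150.0, 150.0)
    concentration: float = 50.0  # Beta concentration of individual ancestry
    ecotone_halfwidth: float = 50.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("cline width must be positive")
        for p in (self.p_left, self.p_right):
            if not 0 <= p <= 1:
                raise ConfigurationError("tail levels must be in [0,1]")

    def habitat_of(self, x: float) -> str:
        if x < -self.ecotone_halfwidth:
            return "desert"
        if x > self.ecotone_halfwidth:
            return "dune"
        return "ecotone"


@dataclass
class CellParams:
    """Outcome model for one habitat x phenotype transplant cell."""

    p_survival: float
    biomass_mean: float
    biomass_sdlog: float = 0.5
    biomass_model: str = "lognormal"
    nb_dispersion: float = 0.5
    cause_probs: dict[str, float] = field(
        default_factory=lambda: {"burial": 0.3, "herbivory": 0.3, "other": 0.4})

    def __post_init__(self) -> None:
        if not 0 <= self.p_survival <= 1:
            raise ConfigurationError("p_survival must be in [0,1]")
        if set(self.cause_probs) != {"burial", "herbivory", "other"}:
            raise ConfigurationError(
                "cause_probs must cover exactly burial/herbivory/other")
        tot = sum(self.cause_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(f"cause probabilities sum to {tot}, not 1")
        if self.biomass_model not in ("lognormal", "nb"):
            raise ConfigurationError(
                f"unknown biomass model {self.biomass_model!r}")


@dataclass
class TransplantConfig:
    """Per-cell parameters plus the number of plants in each cell.

    ``cells`` is keyed by (habitat, phenotype); ``supplemented_cells``
    optionally overrides cells for the water-supplemented treatment.
    """

    cells: dict[tuple[str, str], CellParams]
    n_per_cell: int = 31
    supplemented_cells: dict[tuple[str, str], CellParams] | None = None
    n_supplemented_per_cell: int = 0


@dataclass
class SimConfig:
    """Top-level simulation configuration; ``seed`` fixes every draw."""

    seed: int
    n_loci: int = 1000
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"P1": 20, "P2": 20, "F1": 20, "F2": 20,
                                 "BC1": 20, "BC2": 20})
    n_ref: int = 20
    cline: ClineConfig = field(default_factory=ClineConfig)
    transplant: TransplantConfig | None = None

    def __post_init__(self) -> None:
        bad = set(self.class_counts) - set(CLASSES)
        if bad:
            raise ConfigurationError(f"invalid class names: {sorted(bad)}")


def default_transplant_config(n_per_cell: int = 31) -> TransplantConfig:
    """A divergent-selection default: each parental taxon thrives in its
    own habitat, hybrids do best in the ecotone; burial never kills in
    the desert."""
    desert_causes = {"burial": 0.0, "herbivory": 0.5, "other": 0.5}
    dune_causes = {"burial": 0.6, "herbivory": 0.2, "other": 0.2}
    eco_causes = {"burial": 0.3, "herbivory": 0.3, "other": 0.4}
    s = 0.4
    cells = {
        ("desert", "P1"): CellParams(0.80, 30.0, s, cause_probs=desert_causes),
        ("desert", "P2"): CellParams(0.05, 4.0, s, cause_probs=desert_causes),
        ("desert", "HYB"): CellParams(0.70, 25.0, s, cause_probs=desert_causes),
        ("ecotone", "P1"): CellParams(0.40, 15.0, s, cause_probs=eco_causes),
        ("ecotone", "P2"): CellParams(0.40, 15.0, s, cause_probs=eco_causes),
        ("ecotone", "HYB"): CellParams(0.80, 28.0, s, cause_probs=eco_causes),
        ("dune", "P1"): CellParams(0.03, 3.0, s, cause_probs=dune_causes),
        ("dune", "P2"): CellParams(0.85, 35.0, s, cause_probs=dune_causes),
        ("dune", "HYB"): CellParams(0.30, 12.0, s, cause_probs=dune_causes),
    }
    return TransplantConfig(cells=cells, n_per_cell=n_per_cell)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_class_dosages(rng, cls: str, f1: np.ndarray, f2: np.ndarray,
                        n: int) -> np.ndarray:
    """Dosages for n individuals of a hybrid class at all loci.

    Per locus, the allele-origin state is drawn from the class's origin
    distribution over (both-P1, one-each, both-P2); alleles then come
    from f1/f2 accordingly.
    """
    L = len(f1)
    w = ORIGIN_WEIGHTS[cls]
    state = rng.choice(3, size=(n, L), p=w)
    a1 = rng.random((n, L))
    a2 = rng.random((n, L))
    # allele 1 source: pool1 for states 0,1; pool2 for state 2
    p_a1 = np.where(state <= 1, f1, f2)
    # allele 2 source: pool1 for state 0; pool2 for states 1,2
    p_a2 = np.where(state == 0, f1, f2)
    return (a1 < p_a1).astype(np.int16) + (a2 < p_a2).astype(np.int16)


#: default transect placement per class (meters); P1 is the dune-side taxon
CLASS_POSITION_RANGES = {
    "P1": (60.0, 150.0), "P2": (-150.0, -60.0), "F1": (-40.0, 40.0),
    "F2": (-40.0, 40.0), "BC1": (-50.0, 50.0), "BC2": (-50.0, 50.0),
}


def simulate_genotypes(cfg: SimConfig
                       ) -> tuple[GenotypeMatrix, SampleFrame, dict]:
    """Simulate class-structured genotypes plus reference panels.

    Returns the genotype matrix, a sample frame (reference panels at the
    transect ends, queries placed per class), and a truth dict with true
    class, true admixture proportion, and the true parental frequencies.
    """
    if not cfg.class_counts:
        raise ConfigurationError("class_counts must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    f1, f2 = cfg.divergence.draw(rng, cfg.n_loci)
    locus_ids = [f"L{j}" for j in range(cfg.n_loci)]

    sample_ids, rows, meta, true_class, true_q = [], [], [], {}, {}
    lo, hi = cfg.cline.span

    def add(sid, cls, role, pos):
        sample_ids.append(sid)
        rows.append(_draw_class_dosages(rng, cls, f1, f2, 1)[0])
        meta.append((sid, pos, cfg.cline.habitat_of(pos), role))
        true_class[sid] = cls
        true_q[sid] = CLASS_Q[cls]

    for i in range(cfg.n_ref):
        add(f"ref1_{i}", "P1", "reference_P1", hi)
    for i in range(cfg.n_ref):
        add(f"ref2_{i}", "P2", "reference_P2", lo)
    for cls, n in cfg.class_counts.items():
        a, b = CLASS_POSITION_RANGES[cls]
        for i in range(n):
            add(f"{cls}_{i}", cls, "query", float(rng.uniform(a, b)))

    gm = GenotypeMatrix(sample_ids, locus_ids, np.stack(rows))
    sf = SampleFrame(pd.DataFrame(meta, columns=["sample_id", "position",
                                                 "habitat", "role"]))
    truth = {"true_class": true_class, "true_q": true_q,
             "f1": f1.tolist(), "f2": f2.tolist()}
    return gm, sf, truth


# ---------------------------------------------------------------------------
# transect / cline
# ---------------------------------------------------------------------------

def simulate_transect(cfg: SimConfig, n_individuals: int,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Positions uniform over the transect span and individual ancestry
    drawn Beta-distributed around the tanh cline expectation."""
    cl = cfg.cline
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cl.span
    positions = rng.uniform(lo, hi, n_individuals)
    expected = cline_model(positions, cl.center, cl.width,
                           cl.p_left, cl.p_right)
    p = np.clip(expected, 1e-4, 1 - 1e-4)
    c = cl.concentration
    ancestry = rng.beta(c * p, c * (1 - p))
    return positions, ancestry


def simulate_zone(cfg: SimConfig, n_query: int = 150
                  ) -> tuple[GenotypeMatrix, SampleFrame, MorphTable, dict]:
    """Simulate a full hybrid zone: a continuous ancestry cline along the
    transect, genotypes conditional on individual ancestry, reference
    panels at the transect ends, and ancestry-correlated leaf morphometry.
    """
    rng = np.random.default_rng(cfg.seed)
    f1, f2 = cfg.divergence.draw(rng, cfg.n_loci)
    locus_ids = [f"L{j}" for j in range(cfg.n_loci)]
    cl = cfg.cline
    lo, hi = cl.span

    positions, ancestry = simulate_transect(cfg, n_query, rng=rng)
    sample_ids, rows, meta, true_q = [], [], [], {}
    for i in range(cfg.n_ref):
        sid = f"ref1_{i}"
        sample_ids.append(sid)
        rows.append(rng.binomial(2, f1).astype(np.int16))
        meta.append((sid, hi, "dune", "reference_P1"))
        true_q[sid] = 1.0
    for i in range(cfg.n_ref):
        sid = f"ref2_{i}"
        sample_ids.append(sid)
        rows.append(rng.binomial(2, f2).astype(np.int16))
        meta.append((sid, lo, "desert", "reference_P2"))
        true_q[sid] = 0.0
    for i in range(n_query):
        sid = f"q_{i}"
        pi = ancestry[i] * f1 + (1 - ancestry[i]) * f2
        sample_ids.append(sid)
        rows.append(rng.binomial(2, pi).astype(np.int16))
        meta.append((sid, float(positions[i]),
                     cl.habitat_of(positions[i]), "query"))
        true_q[sid] = float(ancestry[i])

    gm = GenotypeMatrix(sample_ids, locus_ids, np.stack(rows))
    sf = SampleFrame(pd.DataFrame(meta, columns=["sample_id", "position",
                                                 "habitat", "role"]))
    morph = simulate_morphology(sf, true_q, rng)
    truth = {"true_q": true_q, "cline": {
        "center": cl.center, "width": cl.width,
        "p_left": cl.p_left, "p_right": cl.p_right}}
    return gm, sf, morph, truth


def simulate_morphology(sf: SampleFrame, true_q: dict[str, float],
                        rng: np.random.Generator, n_leaves: int = 4,
                        n_shape: int = 3, noise: float = 0.25) -> MorphTable:
    """Leaf table whose measurements load on the ancestry axis.

    Area and ``n_shape`` shape descriptors each shift linearly with
    (2q - 1) plus leaf-level Gaussian noise.
    """
    loadings = np.linspace(1.0, 0.4, n_shape)
    recs = []
    for sid in sf.df["sample_id"]:
        t = 2.0 * true_q[sid] - 1.0
        for leaf in range(n_leaves):
            area = max(0.05, 5.0 + 2.0 * t + rng.normal(0, noise))
            row = {"sample_id": sid, "leaf_id": f"{sid}_leaf{leaf}",
                   "area": area}
            for k in range(n_shape):
                row[f"shape{k+1}"] = loadings[k] * t + rng.normal(0, noise)
            recs.append(row)
    return MorphTable(pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# transplant outcomes
# ---------------------------------------------------------------------------

def _draw_biomass(rng, cell: CellParams, n: int) -> np.ndarray:
    if cell.biomass_model == "lognormal":
        s = cell.biomass_sdlog
        meanlog = np.log(cell.biomass_mean) - s * s / 2.0
        return rng.lognormal(meanlog, s, n)
    # negative binomial with mean m and dispersion alpha (var m + a m^2)
    a = cell.nb_dispersion
    m = cell.biomass_mean
    return rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m), n).astype(float)


def simulate_transplant(cfg: SimConfig) -> tuple[TransplantTable, dict]:
    """Simulate transplant outcomes for every configured cell.

    Survival is Bernoulli per cell; biomass is log-normal (default) or
    negative-binomial with the cell mean; death causes are multinomial
    among burial/herbivory/other for non-survivors. Returns the table
    and a truth dict with expected composite fitness per cell.
    """
    tp = cfg.transplant
    if tp is None:
        raise ConfigurationError("transplant config missing")
    rng = np.random.default_rng(cfg.seed)
    recs = []
    truth_cells = {}
    plans = [("ambient", tp.cells, tp.n_per_cell)]
    if tp.supplemented_cells is not None and tp.n_supplemented_per_cell > 0:
        plans.append(("supplemented", tp.supplemented_cells,
                      tp.n_supplemented_per_cell))
    for water, cells, n_cell in plans:
        for (hab, phe), cell in cells.items():
            surv = rng.random(n_cell) < cell.p_survival
            biomass = _draw_biomass(rng, cell, n_cell)
            causes = np.array(["alive"] * n_cell, dtype=object)
            dead = ~surv
            if dead.any():
                labels = ["burial", "herbivory", "other"]
                probs = [cell.cause_probs[c] for c in labels]
                causes[dead] = rng.choice(labels, size=int(dead.sum()), p=probs)
            for i in range(n_cell):
                recs.append({
                    "plant_id": f"{hab}_{phe}_{water}_{i}",
                    "phenotype": phe, "habitat": hab, "water": water,
                    "survived": int(surv[i]),
                    "biomass": float(biomass[i]),
                    "death_cause": str(causes[i]),
                })
            truth_cells[f"{hab}:{phe}:{water}"] = {
                "p_survival": cell.p_survival,
                "expected_composite": expected_composite(cell),
            }
    tt = TransplantTable(pd.DataFrame(recs))
    truth = {"cells": truth_cells, "true_s": true_selection_coefficients(cfg)}
    return tt, truth


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)


def expected_composite(cell: CellParams) -> float:
    """True expected composite fitness p_survival * E[ln(1+biomass)].

    Lognormal expectation by Gauss-Hermite quadrature; NB expectation by
    direct summation over the bulk of the support.
    """
    if cell.biomass_model == "lognormal":
        s = cell.biomass_sdlog
        meanlog = np.log(cell.biomass_mean) - s * s / 2.0
        vals = np.log1p(np.exp(meanlog + s * _GH_NODES))
        e_log = float((vals * _GH_WEIGHTS).sum() / np.sqrt(2 * np.pi))
    else:
        from scipy.stats import nbinom
        a, m = cell.nb_dispersion, cell.biomass_mean
        r, p = 1.0 / a, 1.0 / (1.0 + a * m)
        kmax = int(nbinom.ppf(1 - 1e-12, r, p)) + 1
        k = np.arange(kmax + 1)
        e_log = float((np.log1p(k) * nbinom.pmf(k, r, p)).sum())
    return cell.p_survival * e_log


def true_selection_coefficients(cfg: SimConfig) -> dict[str, float]:
    """True s per ambient cell implied by the configured outcome model."""
    tp = cfg.transplant
    out = {}
    habs = {h for h, _ in tp.cells}
    for hab in habs:
        comps = {phe: expected_composite(cell)
                 for (h, phe), cell in tp.cells.items() if h == hab}
        top = max(comps.values())
        for phe, c in comps.items():
            out[f"{hab}:{phe}"] = 1.0 - (c / top if top > 0 else np.nan)
    return out


# ---------------------------------------------------------------------------
# fixture writing (text formats only)
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write dosages as a minimal uncompressed VCFv4.2 with GT fields."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, lid in enumerate(gm.locus_ids):
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(f"1\t{j + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
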