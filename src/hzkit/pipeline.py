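"""End-to-end orchestration of the hybrid-zone and transplant analyses.

Two entry points: :func:`run_hybridzone` chains ancestry estimation,
hybrid classification, cline fitting and the morphometric index into a
single zone report; :func:`run_transplant` chains selection-coefficient
estimation, the NB-GLM interaction test and the log-linear mortality
analysis. Both write their stage outputs plus one JSON summary that
embeds a config hash and the package version, and are deterministic
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import estimate_q_all, genotype_morphology_correlation
from .cline import bin_transect_frame, fit_cline
from .errors import HzkitError, ValidationError
from .hybrid_classes import classify_all, zone_composition
from .io_core import (parental_frequencies, read_genotypes, read_morphology,
                      read_samples, read_transplant)
from .morphology import leaf_pca_index
from .mortality import backward_stepwise, table_from_transplant
from .selection import (fit_nb_glm, lr_interaction_test,
                        selection_coefficients, summaries_to_frame)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; seed is mandatory for stochastic stages."""

    genotypes: str | None = None
    genotype_format: str = "tsv012"
    samples: str | None = None
    morphology: str | None = None
    transplant: str | None = None
    out_dir: str = "."
    band_width: float = 10.0
    min_loci: int = 50
    shrinkage: float = 0.5
    class_set: str = "six"
    n_boot: int = 500
    seed: int = 0
    glm_family: str = "nb"
    cline_error_model: str = "normal"
    resample: str = "cell"
    alpha: float = 0.05

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_paths(cfg: RunConfig, required: list[str]) -> None:
    for name in required:
        path = getattr(cfg, name)
        if path is None:
            raise ValidationError(f"config field {name!r} is required")
        if not os.path.exists(path):
            raise ValidationError(f"{name} path does not exist: {path}")


def _stage(name: str):
    """Wrap a stage so failures are reported with the stage name."""
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except HzkitError as exc:
                raise HzkitError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_hybridzone(cfg: RunConfig) -> dict:
    """Genotypes + metadata -> ancestry, classes, cline, morphology index.

    Writes ``q.tsv``, ``assignments.tsv``, ``cline.json`` and
    ``zone_summary.json`` under ``cfg.out_dir`` and returns the summary.
    """
    _check_paths(cfg, ["genotypes", "samples"])
    if cfg.morphology is not None:
        _check_paths(cfg, ["morphology"])
    os.makedirs(cfg.out_dir, exist_ok=True)

    gm = read_genotypes(cfg.genotypes, cfg.genotype_format)
    sf = read_samples(cfg.samples)
    sf.check_paired(gm)
    F = parental_frequencies(gm, sf, shrinkage=cfg.shrinkage)
    query_ids = sf.ids_with_role("query")
    if not query_ids:
        raise HzkitError("stage 'ancestry' failed: empty query set")

    ests = _stage("ancestry")(estimate_q_all)(
        gm, F, sample_ids=query_ids, min_loci=cfg.min_loci)
    q_df = pd.DataFrame([{
        "sample_id": e.sample_id, "q": e.q, "se": e.se,
        "loglik": e.loglik, "n_loci": e.n_loci_used} for e in ests])
    q_df.to_csv(os.path.join(cfg.out_dir, "q.tsv"), sep="\t", index=False)

    from .hybrid_classes import CLASS_SETS
    assignments = _stage("classify")(classify_all)(
        gm, F, sample_ids=query_ids, classes=CLASS_SETS[cfg.class_set],
        min_loci=cfg.min_loci)
    a_rows = []
    for a in assignments:
        row = {"sample_id": a.sample_id, "best_class": a.best_class,
               "n_loci": a.n_loci_used}
        row.update({f"post_{c}": p for c, p in a.posterior.items()})
        a_rows.append(row)
    pd.DataFrame(a_rows).to_csv(
        os.path.join(cfg.out_dir, "assignments.tsv"), sep="\t", index=False)
    composition = zone_composition(assignments, sf)

    bands = _stage("cline")(bin_transect_frame)(ests, sf, cfg.band_width)
    fit = _stage("cline")(fit_cline)(
        bands, error_model=cfg.cline_error_model,
        n_boot=cfg.n_boot, seed=cfg.seed)
    cline_report = {
        "center": fit.center, "width": fit.width, "pmin": fit.pmin,
        "pmax": fit.pmax, "loglik": fit.loglik, "ci_width": fit.ci_width,
        "n_bands": bands.n_bands, "band_width": cfg.band_width}
    with open(os.path.join(cfg.out_dir, "cline.json"), "w") as fh:
        json.dump(cline_report, fh, indent=1, sort_keys=True)

    correlation = None
    if cfg.morphology is not None:
        morph = read_morphology(cfg.morphology)
        indices = _stage("morphology")(leaf_pca_index)(morph, sf)
        idx_by_id = {h.sample_id: h.index for h in indices}
        paired = [(e.q, idx_by_id[e.sample_id]) for e in ests
                  if e.sample_id in idx_by_id]
        if len(paired) >= 3:
            qv, mv = map(np.array, zip(*paired))
            r, p = genotype_morphology_correlation(qv, mv)
            correlation = {"r": r, "p": p, "n": len(paired),
                           "pc1_var_frac": indices[0].pc1_var_frac}

    summary = {
        "config_hash": cfg.digest(), "version": __version__,
        "n_samples": gm.n_samples, "n_loci": F.n_loci,
        "n_dropped_loci": len(F.dropped_loci),
        "composition": composition,
        "cline": cline_report,
        "genotype_morphology_correlation": correlation,
    }
    with open(os.path.join(cfg.out_dir, "zone_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_transplant(cfg: RunConfig) -> dict:
    """TransplantTable -> selection coefficients, GLM LR test, mortality.

    Writes ``fitness.tsv``, ``glm_report.json`` and
    ``transplant_summary.json`` under ``cfg.out_dir``.
    """
    _check_paths(cfg, ["transplant"])
    os.makedirs(cfg.out_dir, exist_ok=True)
    tt = read_transplant(cfg.transplant)

    summaries = _stage("selection")(selection_coefficients)(
        tt, n_boot=cfg.n_boot, seed=cfg.seed, resample=cfg.resample)
    fdf = summaries_to_frame(summaries)
    fdf.to_csv(os.path.join(cfg.out_dir, "fitness.tsv"), sep="\t", index=False)

    df = tt.df.assign(fitness=np.log1p(tt.df["biomass"])
                      * tt.df["survived"].astype(float))
    glm_report: dict = {}
    try:
        full = fit_nb_glm(df, "fitness ~ habitat * phenotype",
                          family=cfg.glm_family)
        reduced = fit_nb_glm(df, "fitness ~ habitat + phenotype",
                             family=cfg.glm_family)
        lr, dof, p = lr_interaction_test(full, reduced)
        glm_report = {"lr": lr, "df": dof, "p": p,
                      "full_loglik": full.loglik,
                      "reduced_loglik": reduced.loglik,
                      "alpha_full": full.alpha}
    except HzkitError as exc:
        logger.warning("GLM stage degraded: %s", exc)
        glm_report = {"error": str(exc)}
    with open(os.path.join(cfg.out_dir, "glm_report.json"), "w") as fh:
        json.dump(glm_report, fh, indent=1, sort_keys=True)

    mortality_report = {}
    for cause in ("burial", "herbivory"):
        if (tt.df["death_cause"] == cause).sum() == 0:
            mortality_report[cause] = {"note": "no deaths from this cause"}
            continue
        tab = table_from_transplant(tt, cause)
        res = _stage("mortality")(backward_stepwise)(tab, alpha=cfg.alpha)
        mortality_report[cause] = {
            "final_model": sorted(sorted(t) for t in res.final_model),
            "three_way_test": res.three_way_test,
            "trail": [{"term": list(r.term), "delta_g2": r.delta_g2,
                       "df": r.df, "p": r.p, "removed": r.removed}
                      for r in res.trail],
        }

    summary = {
        "config_hash": cfg.digest(), "version": __version__,
        "n_plants": len(tt.df),
        "fitness": fdf.to_dict(orient="records"),
        "glm": glm_report,
        "mortality": mortality_report,
    }
    with open(os.path.join(cfg.out_dir, "transplant_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
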