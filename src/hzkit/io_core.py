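"""Domain types, validation, and readers/writers.

Core containers for genotype matrices, per-sample transect metadata,
parental allele frequencies, reciprocal-transplant outcome tables, and
leaf-morphometry tables, plus the TSV/VCF readers and writers that move
them across the file boundary.

Conventions
-----------
* Dosages are counts of the ALT (or "counted") allele in {0, 1, 2};
  missing entries are stored as :data:`MISSING` (-1).
* Transect positions are signed meters from the ecotone midline,
  negative on the desert side, positive on the dune side.
* All internal indexing is 0-based; VCF is 1-based only inside files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Missing-dosage marker used throughout.
MISSING: int = -1

HABITATS = ("desert", "ecotone", "dune")
ROLES = ("reference_P1", "reference_P2", "query")
PHENOTYPES = ("P1", "P2", "HYB")
WATER_LEVELS = ("ambient", "supplemented")
DEATH_CAUSES = ("alive", "burial", "herbivory", "other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, unique.
    locus_ids : list of str
        Column labels, unique.
    dosage : ndarray of int
        Shape ``(n_samples, n_loci)``; entries in ``{0, 1, 2}`` or
        :data:`MISSING`.
    n_skipped_records : int
        Number of input records skipped during reading (non-biallelic or
        non-SNP VCF records); 0 for programmatically built matrices.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.locus_ids):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise ValidationError("locus ids are not unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid dosage {self.dosage[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where dosage is missing."""
        return self.dosage == MISSING

    def row(self, sample_id: str) -> np.ndarray:
        """Dosage vector for one sample."""
        return self.dosage[self.sample_ids.index(sample_id)]


@dataclass
class SampleFrame:
    """Per-individual transect position, habitat, and reference role.

    Wraps a DataFrame with columns ``sample_id``, ``position`` (signed
    meters from the ecotone midline; desert negative), ``habitat`` and
    ``role``, validated against closed vocabularies.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "position", "habitat", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample frame missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample frame")
        bad_h = set(self.df["habitat"]) - set(HABITATS)
        if bad_h:
            raise ValidationError(f"unknown habitat values: {sorted(bad_h)}")
        bad_r = set(self.df["role"]) - set(ROLES)
        if bad_r:
            raise ValidationError(f"unknown role values: {sorted(bad_r)}")
        if not np.isfinite(self.df["position"].to_numpy(float)).all():
            raise ValidationError("non-finite transect position")
        self.df = self.df.reset_index(drop=True)

    def check_paired(self, gm: GenotypeMatrix) -> None:
        """Require every sample here to exist in the genotype matrix."""
        absent = set(self.df["sample_id"]) - set(gm.sample_ids)
        if absent:
            raise ValidationError(
                f"samples absent from genotype matrix: {sorted(absent)[:5]}"
            )

    def ids_with_role(self, role: str) -> list[str]:
        return self.df.loc[self.df["role"] == role, "sample_id"].tolist()

    def position_of(self, sample_id: str) -> float:
        sel = self.df.loc[self.df["sample_id"] == sample_id, "position"]
        if sel.empty:
            raise KeyError(sample_id)
        return float(sel.iloc[0])


@dataclass
class ParentalFrequencies:
    """Per-locus counted-allele frequencies in the two parental pools.

    Frequencies are shrunk (Agresti-style pseudo-alleles) so that no
    value is exactly 0 or 1; ``n1``/``n2`` are the raw allele-count
    denominators before shrinkage. ``dropped_loci`` lists loci removed
    for failing the minimum-allele-count precondition.
    """

    locus_ids: list[str]
    f1: np.ndarray
    f2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    dropped_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        for name, f in (("f1", self.f1), ("f2", self.f2)):
            if f.shape != (len(self.locus_ids),):
                raise ValidationError(f"{name} length mismatch")
            if ((f <= 0) | (f >= 1)).any():
                raise ValidationError(
                    f"{name} contains frequencies at or beyond [0,1] "
                    "boundaries; shrinkage must be applied"
                )

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def swapped(self) -> "ParentalFrequencies":
        """Pools exchanged (f1 <-> f2); used by symmetry tests."""
        return ParentalFrequencies(
            list(self.locus_ids), self.f2.copy(), self.f1.copy(),
            self.n2.copy(), self.n1.copy(), list(self.dropped_loci),
        )


@dataclass
class TransplantTable:
    """Reciprocal-transplant outcomes, one row per plant.

    Columns: ``plant_id``, ``phenotype`` in {P1, P2, HYB}, ``habitat``
    in {desert, ecotone, dune}, ``water`` in {ambient, supplemented},
    ``survived`` binary, ``biomass`` grams >= 0 (biomass at harvest or at
    time of death), ``death_cause`` in {alive, burial, herbivory, other}.
    """

    df: pd.DataFrame

    REQUIRED = ("plant_id", "phenotype", "habitat", "water", "survived",
                "biomass", "death_cause")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"transplant table missing columns: {missing}")
        df = self.df
        if df["plant_id"].duplicated().any():
            raise ValidationError("duplicate plant ids")
        for col, vocab in (("phenotype", PHENOTYPES), ("habitat", HABITATS),
                           ("water", WATER_LEVELS), ("death_cause", DEATH_CAUSES)):
            bad = set(df[col]) - set(vocab)
            if bad:
                raise ValidationError(f"unknown {col} values: {sorted(bad)}")
        surv = df["survived"].to_numpy()
        if not np.isin(surv, (0, 1)).all():
            raise ValidationError("survived must be 0/1")
        alive = df["death_cause"].to_numpy() == "alive"
        if not (alive == (surv == 1)).all():
            raise ValidationError("survived=1 must coincide with death_cause=alive")
        if (df["biomass"].to_numpy(float) < 0).any():
            raise ValidationError("negative biomass")
        if df["biomass"].isna().any():
            raise ValidationError("biomass must be recorded for all plants")
        self.df = df.reset_index(drop=True)


@dataclass
class MorphTable:
    """Leaf-morphometry measurements, one row per leaf.

    Columns: ``sample_id``, ``leaf_id``, then one numeric column per
    measurement (area in cm^2 plus dimensionless shape descriptors).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "leaf_id"):
            if col not in self.df.columns:
                raise ValidationError(f"morph table missing column {col!r}")
        if not self.measurement_columns:
            raise ValidationError("morph table has no measurement columns")
        if "area" in self.df.columns and (self.df["area"].to_numpy(float) < 0).any():
            raise ValidationError("negative leaf area")
        self.df = self.df.reset_index(drop=True)

    @property
    def measurement_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("sample_id", "leaf_id")]

    def check_samples_known(self, sf: SampleFrame) -> None:
        unknown = set(self.df["sample_id"]) - set(sf.df["sample_id"])
        if unknown:
            raise ValidationError(
                f"leaf rows reference unknown samples: {sorted(unknown)[:5]}"
            )


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "tsv012") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or 0/1/2 TSV.

    VCF mode keeps biallelic SNP records only; other records are skipped
    and counted in ``n_skipped_records``. Dosage is the ALT-allele count;
    half-missing genotypes (e.g. ``./1``) are treated as missing.

    TSV mode expects a header ``sample_id<TAB>locus1<TAB>...`` and one
    row per sample with values 0/1/2 or ``NA``.
    """
    if format == "tsv012":
        return _read_tsv012(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def _read_tsv012(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise FormatError(
            f"{path}: first TSV column must be 'sample_id', got {df.columns[0]!r}"
        )
    locus_ids = list(df.columns[1:])
    sample_ids = df["sample_id"].astype(str).tolist()
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosage = np.empty(raw.shape, dtype=np.int16)
    for (i, j), val in np.ndenumerate(raw):
        if isinstance(val, str):
            val = val.strip()
        if val in ("NA", "", ".", None) or (isinstance(val, float) and np.isnan(val)):
            dosage[i, j] = MISSING
        elif val in ("0", "1", "2", 0, 1, 2):
            dosage[i, j] = int(val)
        else:
            raise ValidationError(
                f"{path}: non-0/1/2 value {val!r} at sample "
                f"{sample_ids[i]!r}, locus {locus_ids[j]!r}"
            )
    return GenotypeMatrix(sample_ids, locus_ids, dosage)


def _read_vcf(path: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    try:
        vcf = VCF(path)
        sample_ids = list(vcf.samples)
    except Exception as exc:
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        dos = np.full(len(sample_ids), MISSING, dtype=np.int16)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:  # any missing allele -> missing genotype
                continue
            dos[i] = int(a > 0) + int(b > 0)
        locus_ids.append(f"{rec.CHROM}:{rec.POS}")
        rows.append(dos)
    vcf.close()
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    dosage = (np.stack(rows, axis=1) if rows
              else np.empty((len(sample_ids), 0), dtype=np.int16))
    return GenotypeMatrix(sample_ids, locus_ids, dosage,
                          n_skipped_records=skipped)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write the 0/1/2 TSV dialect read back by :func:`read_genotypes`."""
    df = pd.DataFrame(gm.dosage, columns=gm.locus_ids).astype(object)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample / morph / transplant table I/O
# ---------------------------------------------------------------------------

def read_samples(path: str) -> SampleFrame:
    return SampleFrame(pd.read_csv(path, sep="\t"))


def write_samples(sf: SampleFrame, path: str) -> None:
    sf.df.to_csv(path, sep="\t", index=False)


def read_transplant(path: str) -> TransplantTable:
    return TransplantTable(pd.read_csv(path, sep="\t"))


def write_transplant(tt: TransplantTable, path: str) -> None:
    tt.df.to_csv(path, sep="\t", index=False)


def read_morphology(path: str) -> MorphTable:
    return MorphTable(pd.read_csv(path, sep="\t"))


def write_morphology(mt: MorphTable, path: str) -> None:
    mt.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parental frequency estimation
# ---------------------------------------------------------------------------

def parental_frequencies(
    gm: GenotypeMatrix,
    sf: SampleFrame,
    shrinkage: float = 0.5,
    min_alleles: int = 2,
) -> ParentalFrequencies:
    """Estimate per-locus counted-allele frequencies in both parental pools.

    For each pool the estimate is
    ``f = (allele count + shrinkage) / (denominator + 2 * shrinkage)``,
    i.e. `shrinkage` pseudo-alleles of each type are added so downstream
    class likelihoods are never -inf. Loci with fewer than ``min_alleles``
    non-missing alleles in either pool are dropped and recorded in
    ``dropped_loci``.
    """
    sf.check_paired(gm)
    p1 = sf.ids_with_role("reference_P1")
    p2 = sf.ids_with_role("reference_P2")
    if not p1 or not p2:
        raise ConfigurationError(
            "both reference pools must be non-empty "
            f"(got {len(p1)} reference_P1, {len(p2)} reference_P2)"
        )
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    d1 = gm.dosage[[idx[s] for s in p1]]
    d2 = gm.dosage[[idx[s] for s in p2]]

    def pool_stats(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        present = d != MISSING
        counts = np.where(present, d, 0).sum(axis=0).astype(float)
        denoms = 2.0 * present.sum(axis=0)
        return counts, denoms

    c1, n1 = pool_stats(d1)
    c2, n2 = pool_stats(d2)
    keep = (n1 >= min_alleles) & (n2 >= min_alleles)
    dropped = [lid for lid, k in zip(gm.locus_ids, keep) if not k]
    if dropped:
        logger.info("dropped %d loci with <%d alleles in a reference pool",
                    len(dropped), min_alleles)
    f1 = (c1[keep] + shrinkage) / (n1[keep] + 2 * shrinkage)
    f2 = (c2[keep] + shrinkage) / (n2[keep] + 2 * shrinkage)
    kept_ids = [lid for lid, k in zip(gm.locus_ids, keep) if k]
    return ParentalFrequencies(kept_ids, f1, f2, n1[keep], n2[keep],
                               dropped_loci=dropped)


def subset_to_loci(gm: GenotypeMatrix, locus_ids: list[str]) -> GenotypeMatrix:
    """Column-subset a genotype matrix to the given loci, in order."""
    pos = {l: j for j, l in enumerate(gm.locus_ids)}
    cols = [pos[l] for l in locus_ids]
    return GenotypeMatrix(list(gm.sample_ids), list(locus_ids),
                          gm.dosage[:, cols])
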