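"""Synthetic genotype generation for the whole pipeline.

Two generators cover everything the pipeline consumes, so the repository
builds and tests without any external data:

* five-locus case/control cohorts under Hardy–Weinberg equilibrium with a
  multiplicative per-allele odds disease model — at each locus the
  counted-allele frequency among cases follows the closed form
  ``p' = p*OR / (1 - p + p*OR)`` implied by reweighting HWE genotype
  probabilities by OR^g under the rare-disease approximation;
* wide marker panels with Balding–Nichols population structure (each
  population's frequency drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around a
  shared ancestral frequency p, so the divergence parameter F is the
  expected Hudson-style FST) plus optional pedigree blocks (founder pairs
  and their offspring by gamete dropping) for kinship testing.

``emulate_paper_cohorts`` assembles a full study bundle at the published
cohort sizes (88 SSNS, 139 MCD, 280 SRNS split 121 primary / 159 delayed,
41 FSGS, 49 monogenic, 1108 MN, 5642 healthy controls); monogenic-like
and MN cohorts draw from the unaffected distribution, encoding the
finding that their risk-score distribution is not elevated. The baseline
counted-allele frequencies are illustrative common-variant values, not
calibrated to any real population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import DomainError
from .genotype_io import GenotypeMatrix, VARIANT_COLUMNS, write_vcf
from .risk_model import MISSING, RiskModel, build_default_model

# Illustrative baseline counted-allele frequencies for the five loci.
BASELINE_COUNTED_FREQS = (0.30, 0.40, 0.35, 0.45, 0.20)

# Working coordinates for the five synthetic loci (chrom, pos).
_LOCUS_COORDS = (
    ("6", 32626272),
    ("6", 32681631),
    ("6", 31740763),
    ("6", 116892437),
    ("4", 75439601),
)

PAPER_COHORT_PLAN = (
    # label, subtype, n, role
    ("SSNS", "", 88, "affected"),
    ("MCD", "", 139, "affected"),
    ("SRNS", "primary", 121, "affected"),
    ("SRNS", "delayed", 159, "affected"),
    ("FSGS", "", 41, "affected"),
    ("monogenic", "", 49, "monogenic-like"),
    ("MN", "", 1108, "unaffected"),
    ("healthy", "", 5642, "unaffected"),
)


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort: label, size, disease role and frequencies."""

    label: str
    n: int
    role: str  # affected | unaffected | monogenic-like
    counted_freqs: tuple[float, ...] = BASELINE_COUNTED_FREQS
    prevalence: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("cohort size must be >= 1")
        if self.role not in ("affected", "unaffected", "monogenic-like"):
            raise DomainError(f"unknown cohort role {self.role!r}")
        if any(not (0 < f < 1) for f in self.counted_freqs):
            raise DomainError("counted-allele frequencies must lie in (0, 1)")


@dataclass(frozen=True)
class PedigreeBlock:
    population: int
    n_offspring: int


@dataclass(frozen=True)
class PanelSpec:
    """Wide marker panel with population structure and pedigrees."""

    n_markers: int = 10_000
    n_populations: int = 1
    divergence: float = 0.0  # Balding-Nichols F, the expected FST
    n_per_population: int = 100
    pedigree_blocks: tuple[PedigreeBlock, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.divergence < 1):
            raise DomainError("divergence must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise DomainError("missing rate must lie in [0, 1)")


def case_counted_freq(p: float, or_counted: float) -> float:
    """Counted-allele frequency among cases under multiplicative odds."""
    return p * or_counted / (1.0 - p + p * or_counted)


def _case_genotype_probs_exact(
    freqs: np.ndarray, ors: np.ndarray, prevalence: float
) -> list[np.ndarray]:
    """Per-locus case genotype probabilities under an exact logistic model.

    Solves the intercept so the marginal disease probability equals the
    prevalence, then conditions each locus's HWE genotype probabilities on
    case status. Loci are kept independent given case status, consistent
    with the multiplicative model.
    """
    hwe = [
        np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f]) for f in freqs
    ]
    log_ors = np.log(ors)

    def marginal(alpha: float) -> float:
        # E[expit(alpha + sum_i g_i lnOR_i)] via per-locus moment products
        # of the factorised posterior is not exact for expit; enumerate.
        total = 0.0
        grid = np.zeros(1)
        probs = np.ones(1)
        for h, b in zip(hwe, log_ors):
            grid = (grid[:, None] + b * np.arange(3)[None, :]).ravel()
            probs = (probs[:, None] * h[None, :]).ravel()
        total = float(probs @ expit(alpha + grid))
        return total

    alpha = brentq(
        lambda a: marginal(a) - prevalence, -40, 10, xtol=1e-12
    )
    # joint case distribution, then per-locus marginals
    n_loci = len(hwe)
    combos = np.stack(
        np.meshgrid(*[np.arange(3)] * n_loci, indexing="ij"), axis=-1
    ).reshape(-1, n_loci)
    joint = np.ones(len(combos))
    for i, h in enumerate(hwe):
        joint *= h[combos[:, i]]
    joint *= expit(alpha + combos @ log_ors)
    joint /= joint.sum()
    out = []
    for i in range(n_loci):
        probs_i = np.array([joint[combos[:, i] == g].sum() for g in range(3)])
        out.append(probs_i)
    return out


def simulate_cohort(
    spec: CohortSpec,
    model: RiskModel | None = None,
    sampling: str = "rare",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate one cohort's genotypes at the model loci.

    Unaffected and monogenic-like cohorts draw counted genotypes from HWE
    at the population frequencies. Affected cohorts reweight genotype
    probabilities by OR^g per locus (``sampling='rare'``, the rare-disease
    approximation, equivalent to HWE at the shifted frequency p') or
    condition an exact logistic model on case status at the spec's
    prevalence (``sampling='exact'``).

    Returns the genotype matrix (ALT = effect allele at every locus, so
    harmonisation is genuinely exercised) and a truth table holding each
    sample's counted genotype and the generating parameters.
    """
    model = model or build_default_model()
    if len(spec.counted_freqs) != model.n_loci:
        raise DomainError("frequency vector length != number of model loci")
    rng = np.random.default_rng(spec.seed)
    freqs = np.array(spec.counted_freqs)

    if spec.role == "affected":
        ors = np.exp(model.weights)  # per counted allele, always > 1
        if sampling == "rare":
            shifted = np.array(
                [case_counted_freq(p, o) for p, o in zip(freqs, ors)]
            )
            counted = rng.binomial(2, shifted, size=(spec.n, model.n_loci))
        elif sampling == "exact":
            per_locus = _case_genotype_probs_exact(freqs, ors, spec.prevalence)
            counted = np.column_stack(
                [rng.choice(3, size=spec.n, p=pl) for pl in per_locus]
            )
        else:
            raise DomainError(f"unknown sampling mode {sampling!r}")
    else:
        counted = rng.binomial(2, freqs, size=(spec.n, model.n_loci))

    sample_ids = [f"{spec.label}_{i:04d}" for i in range(spec.n)]
    matrix = counted_to_matrix(counted, sample_ids, model)
    truth = pd.DataFrame(counted, columns=model.marker_ids)
    truth.insert(0, "sample_id", sample_ids)
    truth.insert(1, "cohort", spec.label)
    truth.insert(2, "role", spec.role)
    truth.attrs["spec"] = {
        "label": spec.label,
        "n": spec.n,
        "role": spec.role,
        "counted_freqs": list(spec.counted_freqs),
        "prevalence": spec.prevalence,
        "seed": spec.seed,
        "sampling": sampling,
    }
    return matrix, truth


def counted_to_matrix(
    counted: np.ndarray, sample_ids: Sequence[str], model: RiskModel
) -> GenotypeMatrix:
    """Counted genotypes -> VCF-convention matrix (ALT = effect allele).

    At risk loci the counted allele is the effect allele, so the ALT
    dosage equals the counted dosage; at protective loci the counted
    allele is the non-effect allele, so ALT dosage = 2 - counted. QC
    annotations are filled with passing values (GQ 99, DP 30, OPR 0.99,
    Rsq 0.99).
    """
    counted = np.asarray(counted)
    rows = []
    dosage_cols = []
    for li, locus in enumerate(model.loci):
        chrom, pos = _LOCUS_COORDS[li % len(_LOCUS_COORDS)]
        rows.append(
            {
                "chrom": chrom,
                "pos": pos + li,
                "id": locus.marker_id,
                "ref": locus.other_allele or "N",
                "alt": locus.effect_allele,
                "rsq": 0.99,
                "opr": 0.99,
                "multiallelic": False,
            }
        )
        c = counted[:, li].astype(float)
        c = np.where(c == MISSING, np.nan, c)
        dosage_cols.append(c if locus.direction == "risk" else 2.0 - c)
    dosages = np.column_stack(dosage_cols)
    shape = dosages.shape
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        variants=pd.DataFrame(rows, columns=VARIANT_COLUMNS),
        dosages=dosages,
        gq=np.full(shape, 99.0),
        dp=np.full(shape, 30.0),
        provenance="simulated",
    )


def simulate_panel(
    spec: PanelSpec,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Wide marker panel: structure, pedigrees, missingness, full truth.

    Returns (matrix, sample table, pedigree-pair table). The sample table
    has columns (sample_id, population, is_founder, block); the pair
    table lists every simulated related pair with its relationship
    (``parent-offspring`` or ``full-sib``). Truth frequencies are stored
    in ``matrix.variants`` attrs under ``"population_freqs"``.
    """
    rng = np.random.default_rng(spec.seed)
    p_anc = rng.uniform(0.1, 0.9, size=spec.n_markers)
    F = spec.divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pop_freqs = np.stack(
            [rng.beta(a, b) for _ in range(spec.n_populations)]
        )
    else:
        pop_freqs = np.tile(p_anc, (spec.n_populations, 1))
    pop_freqs = np.clip(pop_freqs, 1e-4, 1 - 1e-4)

    samples: list[dict] = []
    genotypes: list[np.ndarray] = []

    def add_sample(sid: str, pop: int, geno: np.ndarray, founder: bool, block: int) -> None:
        samples.append(
            {"sample_id": sid, "population": f"POP{pop}", "is_founder": founder, "block": block}
        )
        genotypes.append(geno)

    for pop in range(spec.n_populations):
        draws = rng.binomial(
            2, pop_freqs[pop], size=(spec.n_per_population, spec.n_markers)
        )
        for i in range(spec.n_per_population):
            add_sample(f"POP{pop}_S{i:04d}", pop, draws[i], True, -1)

    pairs: list[tuple[str, str, str]] = []
    for bi, block in enumerate(spec.pedigree_blocks):
        pop = block.population
        f1, f2 = rng.binomial(
            2, pop_freqs[pop], size=(2, spec.n_markers)
        )
        id1, id2 = f"PED{bi}_F0", f"PED{bi}_F1"
        add_sample(id1, pop, f1, True, bi)
        add_sample(id2, pop, f2, True, bi)
        kids = []
        for k in range(block.n_offspring):
            gam1 = rng.binomial(1, f1 / 2.0)
            gam2 = rng.binomial(1, f2 / 2.0)
            kid_id = f"PED{bi}_O{k}"
            add_sample(kid_id, pop, gam1 + gam2, False, bi)
            pairs.append((id1, kid_id, "parent-offspring"))
            pairs.append((id2, kid_id, "parent-offspring"))
            kids.append(kid_id)
        for a_idx in range(len(kids)):
            for b_idx in range(a_idx + 1, len(kids)):
                pairs.append((kids[a_idx], kids[b_idx], "full-sib"))

    dosages = np.stack(genotypes).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, spec.n_markers + 1) * 1000,
            "id": [f"snp{i:06d}" for i in range(spec.n_markers)],
            "ref": "A",
            "alt": "G",
            "rsq": np.nan,
            "opr": np.nan,
            "multiallelic": False,
        },
        columns=VARIANT_COLUMNS,
    )
    variants.attrs["population_freqs"] = pop_freqs
    matrix = GenotypeMatrix(
        sample_ids=[s["sample_id"] for s in samples],
        variants=variants,
        dosages=dosages,
        provenance="simulated",
    )
    return (
        matrix,
        pd.DataFrame(samples),
        pd.DataFrame(pairs, columns=["id1", "id2", "relationship"]),
    )


@dataclass
class StudyBundle:
    """A complete synthetic study: genotypes, cohort map and truth."""

    matrix: GenotypeMatrix
    cohorts: pd.DataFrame  # sample_id, cohort, subtype, role
    truth: pd.DataFrame
    model: RiskModel
    seed: int


def emulate_paper_cohorts(
    seed: int,
    model: RiskModel | None = None,
    counted_freqs: tuple[float, ...] = BASELINE_COUNTED_FREQS,
    sampling: str = "rare",
) -> StudyBundle:
    """Full study bundle at the published cohort sizes (7347 samples).

    Affected cohorts (SSNS, MCD, SRNS primary/delayed, FSGS) are sampled
    under the multiplicative-odds case model; monogenic-like, MN and
    healthy cohorts draw from the unaffected population distribution.
    Deterministic given the seed.
    """
    model = model or build_default_model()
    matrices = []
    truth_tables = []
    cohort_rows = []
    for ci, (label, subtype, n, role) in enumerate(PAPER_COHORT_PLAN):
        tag = f"{label}{('_' + subtype) if subtype else ''}"
        spec = CohortSpec(
            label=tag,
            n=n,
            role=role,
            counted_freqs=counted_freqs,
            seed=(seed * 1000 + ci) % (2**31),
        )
        mat, truth = simulate_cohort(
            spec, model, sampling=sampling if role == "affected" else "rare"
        )
        matrices.append(mat)
        truth["cohort"] = label
        truth.insert(2, "subtype", subtype)
        truth_tables.append(truth)
        for sid in mat.sample_ids:
            cohort_rows.append(
                {"sample_id": sid, "cohort": label, "subtype": subtype, "role": role}
            )

    dosages = np.vstack([m.dosages for m in matrices])
    shape = dosages.shape
    matrix = GenotypeMatrix(
        sample_ids=[s for m in matrices for s in m.sample_ids],
        variants=matrices[0].variants.copy(),
        dosages=dosages,
        gq=np.full(shape, 99.0),
        dp=np.full(shape, 30.0),
        provenance="simulated",
    )
    return StudyBundle(
        matrix=matrix,
        cohorts=pd.DataFrame(cohort_rows),
        truth=pd.concat(truth_tables, ignore_index=True),
        model=model,
        seed=seed,
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as VCF + cohort-map TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "study.vcf",
        "cohorts": outdir / "cohorts.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(bundle.matrix, paths["vcf"])
    bundle.cohorts.to_csv(paths["cohorts"], sep="\t", index=False)
    truth = {
        "seed": bundle.seed,
        "cohort_plan": [list(row) for row in PAPER_COHORT_PLAN],
        "counted_genotypes": {
            row["sample_id"]: [int(row[m]) for m in bundle.model.marker_ids]
            for _, row in bundle.truth.iterrows()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=0))
    return paths
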