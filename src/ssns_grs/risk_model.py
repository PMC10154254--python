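"""The five-locus SSNS genetic risk score model.

The score for one individual is

    GRS = sum_i  w_i * c_i / D

where, at locus i, ``w_i = ln(OR_i)`` for a risk locus (OR > 1) or
``w_i = ln(1/OR_i)`` for a protective locus (OR < 1), ``c_i`` is the number
of *counted* alleles carried (the tested risk allele at risk loci, the
non-protective — i.e. opposite — allele at protective loci), and
``D = 2L`` is the total number of possible alleles over the ``L`` loci.
Every weight is therefore positive and the score lives on
``[0, 2*sum(w)/D]``.

Besides per-sample scoring, the module enumerates the exact population
distribution of the score under Hardy–Weinberg equilibrium and independent
loci (3^L genotype vectors — 243 points for the default model), which
serves as a closed-form oracle for medians, quantiles and AUC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    MissingGenotypeError,
    UndefinedScoreError,
)

MISSING = -1  # sentinel for a missing counted-genotype entry

MissingPolicy = Literal["strict", "rescale"]


@dataclass(frozen=True)
class RiskLocus:
    """One weighted locus of the risk model.

    ``direction`` is derived from the odds ratio: risk iff OR > 1. The
    locus weight is ``ln(OR)`` for risk loci and ``ln(1/OR)`` for
    protective loci, so it is positive either way. ``proxy_ids`` lists
    acceptable substitute variants as (rsid, r2) pairs, tightest first.
    """

    marker_id: str
    gene_label: str
    effect_allele: str
    odds_ratio: float
    other_allele: str | None = None
    proxy_ids: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise DomainError(f"{self.marker_id}: odds ratio must be > 0")
        if self.odds_ratio == 1.0:
            raise DomainError(
                f"{self.marker_id}: OR = 1 carries zero weight and no "
                "direction; such loci are rejected"
            )

    @property
    def direction(self) -> str:
        return "risk" if self.odds_ratio > 1 else "protective"

    @property
    def weight(self) -> float:
        """ln(OR) if risk, ln(1/OR) if protective — always positive."""
        return abs(math.log(self.odds_ratio))

    @property
    def counted_allele(self) -> str | None:
        """Allele whose dosage enters the score.

        The effect allele at risk loci; the *other* allele at protective
        loci (the non-protective allele). May be None for protective loci
        read from tabular sources that do not carry the other allele.
        """
        if self.direction == "risk":
            return self.effect_allele
        return self.other_allele


@dataclass(frozen=True)
class RiskModel:
    """Ordered collection of risk loci with the 2L-allele denominator."""

    loci: tuple[RiskLocus, ...]

    def __post_init__(self) -> None:
        ids = [l.marker_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise DomainError("duplicate marker ids in risk model")
        if not self.loci:
            raise DomainError("risk model needs at least one locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def denominator(self) -> int:
        """Total number of possible alleles: two per locus."""
        return 2 * len(self.loci)

    @property
    def weights(self) -> np.ndarray:
        return np.array([l.weight for l in self.loci])

    @property
    def max_score(self) -> float:
        return float(2 * self.weights.sum() / self.denominator)

    @property
    def marker_ids(self) -> list[str]:
        return [l.marker_id for l in self.loci]


@dataclass
class GrsResult:
    """Per-sample score with provenance."""

    sample_id: str
    score: float
    per_locus_contribution: list[float]
    n_loci_used: int
    proxy_used: list[bool]
    missing_policy_applied: MissingPolicy


# The five loci: marker, gene, tested allele, other allele, odds ratio.
# The tested alleles and odds ratios are the published ones; the other
# alleles are a working convention (the publication does not list them)
# and are what the synthetic-data generator emits. Override via a model
# file when scoring real data whose alternate alleles differ.
_DEFAULT_LOCI = (
    ("rs9273542", "HLA-DQB1", "T", "G", 3.39),
    ("rs2858317", "HLA-DQB1", "C", "T", 0.37),
    ("rs3828799", "HLA-DQB1", "C", "T", 1.81),
    ("rs2637678", "CALHM6", "C", "T", 0.51),
    ("rs10518133", "PARM1", "A", "G", 1.96),
)


def build_default_model() -> RiskModel:
    """The published five-locus SSNS model (denominator 10)."""
    return RiskModel(
        loci=tuple(
            RiskLocus(
                marker_id=m,
                gene_label=g,
                effect_allele=ea,
                other_allele=oa,
                odds_ratio=orr,
            )
            for m, g, ea, oa, orr in _DEFAULT_LOCI
        )
    )


def load_model(path: str | Path) -> RiskModel:
    """Read a risk model from a tab-separated file.

    Columns: marker_id, gene, effect_allele, other_allele, odds_ratio,
    proxy_ids (semicolon-separated ``id:r2`` pairs, may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "gene", "effect_allele", "odds_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"risk-model file missing columns: {sorted(missing)}")
    loci = []
    for _, row in df.iterrows():
        proxies: tuple[tuple[str, float], ...] = ()
        raw = row.get("proxy_ids")
        if isinstance(raw, str) and raw.strip():
            proxies = tuple(
                (p.split(":")[0], float(p.split(":")[1]))
                for p in raw.split(";")
                if p.strip()
            )
        other = row.get("other_allele")
        loci.append(
            RiskLocus(
                marker_id=row["marker_id"],
                gene_label=row["gene"],
                effect_allele=row["effect_allele"],
                other_allele=other if isinstance(other, str) and other else None,
                odds_ratio=float(row["odds_ratio"]),
                proxy_ids=proxies,
            )
        )
    return RiskModel(loci=tuple(loci))


def save_model(model: RiskModel, path: str | Path) -> None:
    rows = []
    for l in model.loci:
        rows.append(
            {
                "marker_id": l.marker_id,
                "gene": l.gene_label,
                "effect_allele": l.effect_allele,
                "other_allele": l.other_allele or "",
                "odds_ratio": l.odds_ratio,
                "proxy_ids": ";".join(f"{p}:{r}" for p, r in l.proxy_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_grs(
    model: RiskModel,
    counted: Sequence[int],
    sample_id: str = "",
    missing_policy: MissingPolicy = "strict",
    proxy_used: Sequence[bool] | None = None,
) -> GrsResult:
    """Score one sample from its counted-allele genotype vector.

    ``counted`` holds, per locus in model order, the number of counted
    alleles in {0, 1, 2} or ``MISSING`` (-1). Under ``strict`` any missing
    locus raises; under ``rescale`` the denominator shrinks to twice the
    number of observed loci, keeping the score on the same 0..max scale.
    """
    counted = list(counted)
    if len(counted) != model.n_loci:
        raise DomainError(
            f"genotype length {len(counted)} != model loci {model.n_loci}"
        )
    for c in counted:
        if c not in (0, 1, 2, MISSING):
            raise DomainError(f"counted-allele value {c!r} not in {{0,1,2,missing}}")

    observed = [c != MISSING for c in counted]
    n_used = sum(observed)
    if missing_policy == "strict":
        if n_used < model.n_loci:
            bad = [
                l.marker_id for l, ok in zip(model.loci, observed) if not ok
            ]
            raise MissingGenotypeError(
                f"missing genotype at {bad} under strict policy"
            )
    elif missing_policy == "rescale":
        if n_used == 0:
            raise UndefinedScoreError("all loci missing; score undefined")
    else:
        raise DomainError(f"unknown missing policy {missing_policy!r}")

    denom = 2 * n_used if missing_policy == "rescale" else model.denominator
    contributions = [
        (l.weight * c if c != MISSING else 0.0)
        for l, c in zip(model.loci, counted)
    ]
    score = sum(contributions) / denom
    return GrsResult(
        sample_id=sample_id,
        score=score,
        per_locus_contribution=contributions,
        n_loci_used=n_used,
        proxy_used=list(proxy_used) if proxy_used is not None else [False] * model.n_loci,
        missing_policy_applied=missing_policy,
    )


def score_matrix(
    model: RiskModel,
    counted: np.ndarray,
    sample_ids: Sequence[str],
    missing_policy: MissingPolicy = "strict",
) -> pd.DataFrame:
    """Vectorised scoring of a samples x loci counted-allele matrix.

    Returns a DataFrame (sample_id, score, n_loci_used). Semantics match
    :func:`compute_grs` applied row-wise.
    """
    counted = np.asarray(counted, dtype=float)
    counted = np.where(counted == MISSING, np.nan, counted)
    obs = ~np.isnan(counted)
    n_used = obs.sum(axis=1)
    if missing_policy == "strict":
        if (n_used < model.n_loci).any():
            raise MissingGenotypeError(
                "missing genotypes present under strict policy"
            )
        denom = np.full(len(counted), model.denominator, dtype=float)
    else:
        if (n_used == 0).any():
            raise UndefinedScoreError("a sample has all loci missing")
        denom = 2.0 * n_used
    w = model.weights
    num = np.nansum(counted * w, axis=1)
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "score": num / denom,
            "n_loci_used": n_used.astype(int),
        }
    )


def _hwe_probs(freq: float) -> np.ndarray:
    """P(counted count = 0, 1, 2) under HWE at counted-allele frequency p."""
    q = 1.0 - freq
    return np.array([q * q, 2 * freq * q, freq * freq])


def exact_score_distribution(
    model: RiskModel, counted_allele_freqs: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution under HWE with independent loci.

    Enumerates all 3^L counted-genotype vectors. Returns (scores, probs),
    scores strictly increasing, probs summing to 1. Scores that coincide
    to within 1e-12 are merged.
    """
    freqs = np.asarray(counted_allele_freqs, dtype=float)
    if len(freqs) != model.n_loci:
        raise DomainError("frequency vector length != number of loci")
    if ((freqs < 0) | (freqs > 1)).any():
        raise DomainError("counted-allele frequencies must lie in [0, 1]")

    per_locus = [_hwe_probs(f) for f in freqs]
    w = model.weights
    D = model.denominator
    acc: dict[float, float] = {}
    for combo in itertools.product((0, 1, 2), repeat=model.n_loci):
        p = 1.0
        for probs, c in zip(per_locus, combo):
            p *= probs[c]
        if p == 0.0:
            continue
        s = round(float(np.dot(w, combo) / D), 12)
        acc[s] = acc.get(s, 0.0) + p
    scores = np.array(sorted(acc))
    probs = np.array([acc[s] for s in scores])
    assert abs(probs.sum() - 1.0) < 1e-12
    return scores, probs


def distribution_quantile(
    scores: np.ndarray, probs: np.ndarray, q: float | Sequence[float]
) -> np.ndarray:
    """Quantile(s) of a discrete distribution (left-continuous inverse CDF)."""
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    cdf = np.cumsum(probs)
    idx = np.searchsorted(cdf, qs, side="left")
    return scores[np.clip(idx, 0, len(scores) - 1)]


def exact_median(scores: np.ndarray, probs: np.ndarray) -> float:
    return float(distribution_quantile(scores, probs, 0.5)[0])


def exact_auc(
    model: RiskModel,
    freqs_group1: Sequence[float],
    freqs_group2: Sequence[float],
) -> float:
    """P(S1 > S2) + 0.5 P(S1 = S2) by convolving the two exact distributions.

    The closed-form twin of an empirical ROC AUC with group 1 as the
    positive class.
    """
    s1, p1 = exact_score_distribution(model, freqs_group1)
    s2, p2 = exact_score_distribution(model, freqs_group2)
    gt = (s1[:, None] > s2[None, :]).astype(float)
    eq = (s1[:, None] == s2[None, :]).astype(float)
    return float(p1 @ (gt + 0.5 * eq) @ p2)


def sample_hwe_genotypes(
    freqs: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x L counted-allele counts drawn under HWE (two binomial trials)."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise DomainError("frequencies must lie in [0, 1]")
    return rng.binomial(2, freqs, size=(n, len(freqs)))
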