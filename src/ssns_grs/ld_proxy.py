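"""Pairwise LD r² and proxy-SNP substitution for absent risk loci.

When an index risk SNP is missing from a genotype set, a substitute in
tight linkage disequilibrium (r² > 0.8) is used instead, preferring the
highest-quality candidate and, among equals, the tightest LD. r² is the
squared Pearson correlation of unphased allele dosages (composite /
Rogers–Huff), which requires no phase and equals the haplotype r² under
Hardy–Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import NoProxyError, UndefinedLdError
from .genotype_io import GenotypeMatrix
from .risk_model import RiskLocus

R2_MIN_DEFAULT = 0.8


@dataclass(frozen=True)
class LdEstimate:
    variant_a: str
    variant_b: str
    r2: float
    n_informative: int
    sign: int  # sign of the unsquared dosage correlation


@dataclass(frozen=True)
class ProxyChoice:
    index_id: str
    chosen_id: str
    r2: float
    is_proxy: bool
    source: str  # "index" | "precomputed" | "panel"


def genotype_r2(
    dosages_a: Sequence[float],
    dosages_b: Sequence[float],
    variant_a: str = "a",
    variant_b: str = "b",
) -> LdEstimate:
    """Composite (dosage-correlation) r² with pairwise deletion of missing.

    Raises UndefinedLdError when fewer than two informative pairs remain
    or either variant is monomorphic among them.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise UndefinedLdError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise UndefinedLdError("fewer than 2 informative genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLdError("monomorphic variant among informative pairs")
    r = np.corrcoef(a, b)[0, 1]
    return LdEstimate(
        variant_a=variant_a,
        variant_b=variant_b,
        r2=float(r * r),
        n_informative=int(len(a)),
        sign=int(np.sign(r)) or 1,
    )


def select_proxy(
    model_locus: RiskLocus,
    available_variants: Sequence[str],
    ld_source: GenotypeMatrix | Mapping[str, float] | None = None,
    r2_min: float = R2_MIN_DEFAULT,
    quality_metric: Mapping[str, float] | None = None,
) -> ProxyChoice:
    """Pick the variant standing in for a model locus.

    The index SNP itself wins outright when present. Otherwise candidates
    are ranked by (quality, r², id) and must exceed ``r2_min`` strictly.
    ``ld_source`` supplies r²: either a genotype panel containing the
    index SNP (r² computed on the fly) or a precomputed {candidate: r²}
    mapping; when None, the locus's own ``proxy_ids`` list is used.
    ``quality_metric`` maps candidate id -> quality (imputation Rsq or
    call rate); unlisted candidates get quality 0.
    """
    available = list(available_variants)
    if model_locus.marker_id in available:
        return ProxyChoice(
            index_id=model_locus.marker_id,
            chosen_id=model_locus.marker_id,
            r2=1.0,
            is_proxy=False,
            source="index",
        )

    r2_of: dict[str, float] = {}
    source = "precomputed"
    if ld_source is None:
        r2_of = {pid: r2 for pid, r2 in model_locus.proxy_ids if pid in available}
    elif isinstance(ld_source, Mapping):
        r2_of = {k: v for k, v in ld_source.items() if k in available}
    else:
        source = "panel"
        ids = list(ld_source.variants["id"])
        if model_locus.marker_id in ids:
            idx_col = ids.index(model_locus.marker_id)
            for cand in available:
                if cand not in ids:
                    continue
                try:
                    est = genotype_r2(
                        ld_source.dosages[:, idx_col],
                        ld_source.dosages[:, ids.index(cand)],
                    )
                except UndefinedLdError:
                    continue
                r2_of[cand] = est.r2

    passing = {k: v for k, v in r2_of.items() if v > r2_min}
    if not passing:
        raise NoProxyError(
            f"{model_locus.marker_id}: no available variant with r2 > {r2_min}"
        )
    q = quality_metric or {}
    # Best quality first, then tightest LD, then lexicographically first id.
    best = min(passing, key=lambda k: (-q.get(k, 0.0), -passing[k], k))
    return ProxyChoice(
        index_id=model_locus.marker_id,
        chosen_id=best,
        r2=float(passing[best]),
        is_proxy=True,
        source=source,
    )
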