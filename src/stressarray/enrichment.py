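"""Binomial Gene Ontology enrichment with Benjamini-Hochberg FDR.

For a category with ``n`` annotated genes of which ``x`` are differentially
expressed, and a global differential-expression frequency ``p`` over the
chosen universe, significance is the upper-tail binomial probability
``P(X >= x)`` for ``X ~ Binomial(n, p)``, summed in log space for numerical
stability. Categories with fewer than 20 genes are excluded by default, and
p-values are corrected per ontology stratum with the BH step-up procedure.
The tail direction is an analysis choice (enrichment, not depletion) and is
recorded in every result table; a two-sided variant is available.

Upstream fold thresholds differ by ontology in this workflow: cellular
component uses the 2-fold up-set, molecular function and biological process
the 2.5-fold up-set. ``enrich`` records the threshold it was given; the
pipeline enforces the pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import EnrichmentInputError, ParseError

log = logging.getLogger(__name__)

ONTOLOGIES = ("BP", "MF", "CC")


@dataclass
class GOAnnotation:
    """Flat term -> gene-set annotation (no DAG ancestor propagation)."""

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    ontology: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def genes(self) -> frozenset[str]:
        """All genes with at least one annotation."""
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return frozenset(out)

    def restrict(self, ontology: str) -> "GOAnnotation":
        keep = {t: g for t, g in self.terms.items()
                if self.ontology.get(t, "BP") == ontology}
        return GOAnnotation(
            terms=keep,
            ontology={t: ontology for t in keep},
            names={t: self.names.get(t, t) for t in keep},
        )


def load_annotation(source, fmt: str = "tsv", ontology: str = "BP") -> GOAnnotation:
    """Load a two-column (gene_id, term_id) TSV or a GMT file.

    Duplicate (gene, term) pairs are deduplicated. The two-column dialect
    carries no ontology metadata, so every term is assigned ``ontology``; an
    optional third TSV column overrides it per pair.
    """
    if fmt not in ("tsv", "gmt"):
        raise ParseError(f"unknown annotation format {fmt!r}")
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    ann = GOAnnotation()
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if fmt == "gmt":
            if len(fields) < 3:
                raise ParseError(f"malformed GMT line {lineno}: need term, description, genes")
            term, desc, genes = fields[0], fields[1], fields[2:]
            terms.setdefault(term, set()).update(g for g in genes if g)
            ann.names[term] = desc
            ann.ontology.setdefault(term, ontology)
        else:
            if len(fields) < 2:
                raise ParseError(f"malformed annotation line {lineno}: need gene_id<TAB>term_id")
            gene, term = fields[0], fields[1]
            if gene == "gene_id" and term == "term_id" and lineno == 1:
                continue  # optional header
            terms.setdefault(term, set()).add(gene)
            ann.ontology.setdefault(term, fields[2] if len(fields) > 2 else ontology)
    if not terms:
        log.warning("annotation source is empty")
    ann.terms = {t: frozenset(g) for t, g in terms.items()}
    for t in ann.terms:
        ann.names.setdefault(t, t)
    return ann


def write_annotation(ann: GOAnnotation, path, fmt: str = "tsv") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if fmt == "gmt":
            for term in sorted(ann.terms):
                genes = "\t".join(sorted(ann.terms[term]))
                fh.write(f"{term}\t{ann.names.get(term, term)}\t{genes}\n")
        else:
            fh.write("gene_id\tterm_id\tontology\n")
            for term in sorted(ann.terms):
                ont = ann.ontology.get(term, "BP")
                for gene in sorted(ann.terms[term]):
                    fh.write(f"{gene}\t{term}\t{ont}\n")


def filter_min_size(ann: GOAnnotation, min_size: int = 20,
                    universe: set[str] | None = None) -> GOAnnotation:
    """Keep only terms with at least ``min_size`` genes in the universe."""
    out = GOAnnotation()
    for term, genes in ann.terms.items():
        members = genes if universe is None else genes & frozenset(universe)
        if len(members) >= min_size:
            out.terms[term] = frozenset(members)
            out.ontology[term] = ann.ontology.get(term, "BP")
            out.names[term] = ann.names.get(term, term)
    return out


def binomial_pvalue(n: int, x: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= x), X ~ Binomial(n, p).

    Computed as a log-space sum of exact pmf terms (gammaln + logsumexp),
    accurate into the far tail.
    """
    n = int(n)
    x = int(x)
    if x < 0 or x > n:
        raise EnrichmentInputError(f"x must satisfy 0 <= x <= n (got x={x}, n={n})")
    if not (0.0 <= p <= 1.0):
        raise EnrichmentInputError(f"p must lie in [0, 1] (got p={p})")
    if x <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    k = np.arange(x, n + 1, dtype=float)
    log_pmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p) + (n - k) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def binomial_pvalue_lower(n: int, x: int, p: float) -> float:
    """Lower-tail probability P(X <= x)."""
    if x >= n:
        return 1.0
    return 1.0 - binomial_pvalue(n, x + 1, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise EnrichmentInputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _sig_class(pvalue: float, qvalue: float, nominal_alpha: float, fdr_alpha: float) -> str:
    if qvalue <= fdr_alpha:
        return "fdr"
    if pvalue <= nominal_alpha:
        return "nominal"
    return "none"


def enrich(de_genes, universe, annotation: GOAnnotation, ontology: str | None = None,
           tail: str = "upper", nominal_alpha: float = 0.05, fdr_alpha: float = 0.05,
           strata: str = "ontology", fold_threshold_used: float | None = None,
           direction: str = "up") -> pd.DataFrame:
    """Per-term binomial enrichment of ``de_genes`` within ``universe``.

    Returns a DataFrame (term_id, ontology, name, n, x, p, pvalue, qvalue,
    sig_class) sorted by p-value then term_id. BH correction is applied
    within ontology strata by default (``strata='global'`` pools all terms).
    The frame's ``attrs`` record the universe size, tail, direction and the
    upstream fold threshold.
    """
    de = frozenset(de_genes)
    uni = frozenset(universe)
    outside = sorted(de - uni)
    if outside:
        shown = ", ".join(outside[:10])
        raise EnrichmentInputError(
            f"{len(outside)} DE gene(s) outside the universe: {shown}"
        )
    if tail not in ("upper", "two"):
        raise EnrichmentInputError(f"unknown tail {tail!r}")
    if strata not in ("ontology", "global"):
        raise EnrichmentInputError(f"unknown strata {strata!r}")
    p_global = len(de) / len(uni) if uni else 0.0

    rows = []
    terms = annotation.terms
    for term in sorted(terms):
        ont = annotation.ontology.get(term, "BP")
        if ontology is not None and ont != ontology:
            continue
        members = terms[term] & uni
        n = len(members)
        if n == 0:
            continue
        x = len(members & de)
        pv = binomial_pvalue(n, x, p_global)
        if tail == "two":
            pv = min(1.0, 2.0 * min(pv, binomial_pvalue_lower(n, x, p_global)))
        rows.append({
            "term_id": term,
            "ontology": ont,
            "name": annotation.names.get(term, term),
            "n": n,
            "x": x,
            "p": p_global,
            "pvalue": pv,
        })
    result = pd.DataFrame(rows, columns=["term_id", "ontology", "name",
                                         "n", "x", "p", "pvalue"])
    if len(result):
        qv = np.empty(len(result))
        if strata == "ontology":
            for ont in result["ontology"].unique():
                mask = (result["ontology"] == ont).to_numpy()
                qv[mask] = bh_adjust(result.loc[mask, "pvalue"])
        else:
            qv[:] = bh_adjust(result["pvalue"])
        result["qvalue"] = qv
        result["sig_class"] = [
            _sig_class(p, q, nominal_alpha, fdr_alpha)
            for p, q in zip(result["pvalue"], result["qvalue"])
        ]
        result = result.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        result["qvalue"] = np.array([], dtype=float)
        result["sig_class"] = np.array([], dtype=object)
    result.attrs.update({
        "universe_size": len(uni),
        "de_size": len(de),
        "tail": tail,
        "direction": direction,
        "strata": strata,
        "fold_threshold_used": fold_threshold_used,
        "nominal_alpha": nominal_alpha,
        "fdr_alpha": fdr_alpha,
    })
    return result


@dataclass
class HeatmapMatrix:
    """Rectangular term x condition significance matrices.

    ``pvalue``/``qvalue`` hold NaN and ``sig_class`` holds ``"not_tested"``
    where a term was filtered out of a condition.
    """

    pvalue: pd.DataFrame
    qvalue: pd.DataFrame
    sig_class: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for term in self.pvalue.index:
            for cond in self.pvalue.columns:
                rows.append({
                    "term_id": term,
                    "condition": cond,
                    "pvalue": self.pvalue.loc[term, cond],
                    "qvalue": self.qvalue.loc[term, cond],
                    "sig_class": self.sig_class.loc[term, cond],
                })
        return pd.DataFrame(rows)


def heatmap_matrix(results_by_condition: dict[str, pd.DataFrame]) -> HeatmapMatrix:
    """Assemble per-condition enrichment results into term x condition
    matrices of (pvalue, qvalue, sig_class)."""
    conditions = list(results_by_condition)
    terms: dict[str, None] = {}
    for res in results_by_condition.values():
        for t in res["term_id"]:
            terms.setdefault(t, None)
    index = sorted(terms)
    pv = pd.DataFrame(np.nan, index=index, columns=conditions, dtype=float)
    qv = pd.DataFrame(np.nan, index=index, columns=conditions, dtype=float)
    sc = pd.DataFrame("not_tested", index=index, columns=conditions, dtype=object)
    for cond, res in results_by_condition.items():
        for row in res.itertuples(index=False):
            pv.loc[row.term_id, cond] = row.pvalue
            qv.loc[row.term_id, cond] = row.qvalue
            sc.loc[row.term_id, cond] = row.sig_class
    pv.index.name = qv.index.name = sc.index.name = "term_id"
    return HeatmapMatrix(pvalue=pv, qvalue=qv, sig_class=sc)
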