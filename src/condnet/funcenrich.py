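"""Term enrichment of module gene sets (DAVID-style Fisher tests).

Vocabularies (GO, Reactome, Pfam, ...) arrive as GMT files: one term per
line, ``term_id<TAB>label<TAB>gene1<TAB>gene2...``.  Each (module, term)
pair gets a one-sided Fisher's exact test of the overlap against the
background universe — by default the genes of the analyzed network, not
the whole genome, conditioning on what was measured.  Raw p-values are
reported (with an optional Benjamini-Hochberg column); significance is
flagged at a configurable alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["TermAnnotation", "load_terms", "term_test", "enrich_modules"]


@dataclass(frozen=True)
class TermAnnotation:
    vocabulary: str
    term_id: str
    label: str
    genes: frozenset[str]


@dataclass(frozen=True)
class ModuleEnrichmentRecord:
    module: str
    vocabulary: str
    term_id: str
    label: str
    n_overlap: int
    n_module: int
    n_term: int
    n_background: int
    p: float
    significant: bool


def load_terms(
    paths, background: set[str] | None = None
) -> list[TermAnnotation]:
    """Parse GMT files into term annotations.

    The vocabulary name is the file stem.  Genes outside ``background``
    (when given) are dropped with a logged count; terms left empty are
    dropped with a warning.  Duplicate term IDs within a vocabulary and
    malformed lines are hard errors.
    """
    from pathlib import Path

    if isinstance(paths, (str, Path)):
        paths = [paths]
    terms: list[TermAnnotation] = []
    for path in paths:
        path = Path(path)
        vocab = path.stem
        seen: set[str] = set()
        n_dropped_genes = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: malformed GMT line "
                        f"(need term, label, >=1 gene)"
                    )
                term_id, label, *genes = fields
                if term_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
                seen.add(term_id)
                gene_set = {g for g in genes if g}
                if background is not None:
                    kept = gene_set & background
                    n_dropped_genes += len(gene_set) - len(kept)
                    gene_set = kept
                if not gene_set:
                    logger.warning("term %s has no background genes; dropped", term_id)
                    continue
                terms.append(TermAnnotation(vocab, term_id, label, frozenset(gene_set)))
        if n_dropped_genes:
            logger.info("load_terms(%s): %d annotated genes outside background dropped",
                        path.name, n_dropped_genes)
    return terms


def term_test(
    gene_set: set[str],
    term: TermAnnotation,
    background: set[str],
    module: str = "",
    alpha: float = 0.001,
) -> ModuleEnrichmentRecord:
    """One-sided Fisher's exact test of gene_set x term over background."""
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    term_genes = set(term.genes) & background
    n_bg = len(background)
    n_mod = len(gene_set)
    n_term = len(term_genes)
    overlap = len(gene_set & term_genes)
    if n_mod == 0 or n_term in (0, n_bg):
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, n_term, n_mod))
    return ModuleEnrichmentRecord(
        module=module,
        vocabulary=term.vocabulary,
        term_id=term.term_id,
        label=term.label,
        n_overlap=overlap,
        n_module=n_mod,
        n_term=n_term,
        n_background=n_bg,
        p=min(p, 1.0),
        significant=p < alpha,
    )


def enrich_modules(
    module_sets: dict[str, set[str]],
    terms: list[TermAnnotation],
    background: set[str],
    alpha: float = 0.001,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Test every (module, term) pair; return a tidy record table.

    Rows are sorted by ascending p.  With ``bh_correct`` a
    Benjamini-Hochberg column ``q`` (over all tests) is appended and the
    significance flag applies to ``q`` instead of ``p``.
    """
    records = [
        term_test(genes, term, background, module=mod, alpha=alpha)
        for mod, genes in module_sets.items()
        for term in terms
    ]
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    if bh_correct:
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["q"] < alpha
    return df.sort_values("p", kind="stable").reset_index(drop=True)
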