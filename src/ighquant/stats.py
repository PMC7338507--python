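"""Cohort-level expression statistics.

Operates on an expression matrix (pandas DataFrame, samples × genes, log2
scale throughout: log2(FPKM+1) for whole-transcriptome genes, log2 counts per
base per million for the Ig classes).  Provides correlation matrices,
marker-mean immune metagene scores, clinico-pathological group comparisons,
and Fisher-exact gene-set enrichment of the top-k correlated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

logger = logging.getLogger(__name__)


class CohortStatsError(ValueError):
    pass


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the samples × genes matrix: unique labels, finite values."""
    if expr.index.has_duplicates:
        raise CohortStatsError("duplicated sample identifiers")
    if expr.columns.has_duplicates:
        raise CohortStatsError("duplicated gene identifiers")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise CohortStatsError("expression matrix contains missing/non-finite values")
    return expr


@dataclass(frozen=True)
class MetageneDefinition:
    """A named, distinct marker gene list summarized by its mean log2 expression."""

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise CohortStatsError(f"metagene {self.name!r} has no markers")
        if len(set(self.markers)) != len(self.markers):
            raise CohortStatsError(f"metagene {self.name!r} has duplicate markers")


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of scoreable genes."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        restricted = {
            name: sorted(set(genes) & uni) for name, genes in self.sets.items()
        }
        empty = [name for name, genes in restricted.items() if not genes]
        if empty:
            raise CohortStatsError(
                f"gene sets empty after intersection with universe: {empty[:5]}"
            )
        self.sets = restricted


def correlation_matrix(
    expr: pd.DataFrame, genes: Sequence[str] | None = None, method: str = "pearson"
) -> pd.DataFrame:
    """Symmetric gene-gene correlation matrix (Pearson or Spearman).

    Zero-variance genes yield NaN rows/columns (reported missing, never 0);
    Spearman uses average ranks for ties.
    """
    if method not in ("pearson", "spearman"):
        raise CohortStatsError(f"unknown correlation method {method!r}")
    sub = expr if genes is None else expr.loc[:, list(genes)]
    validate_expression_matrix(sub)
    if len(sub) < 3:
        raise CohortStatsError("correlation requires at least 3 samples")
    return sub.corr(method=method)


def metagene_score(expr: pd.DataFrame, definition: MetageneDefinition) -> pd.Series:
    """Per-sample metagene score: mean log2 expression over present markers."""
    present = [m for m in definition.markers if m in expr.columns]
    absent = set(definition.markers) - set(present)
    if absent:
        logger.warning(
            "metagene %s: %d markers absent from matrix", definition.name, len(absent)
        )
    if not present:
        raise CohortStatsError(
            f"metagene {definition.name!r}: no marker present in matrix"
        )
    # fixed summation order so the score is exactly marker-order invariant
    score = expr.loc[:, sorted(present)].mean(axis=1)
    score.name = definition.name
    return score


def group_compare(
    values: pd.Series, groups: pd.Series, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test of expression between two groups (Welch by default).

    Returns (t statistic, two-sided p).  Group orientation: the statistic is
    positive when the first group label (sorted order) has the higher mean.
    """
    values, groups = values.align(groups, join="inner")
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise CohortStatsError(f"need exactly 2 group levels, got {levels}")
    a = values[groups == levels[0]].dropna()
    b = values[groups == levels[1]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise CohortStatsError("each group needs at least 2 samples")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def age_trend(values: pd.Series, age: pd.Series) -> tuple[float, float]:
    """OLS of expression on age in years; returns (slope, two-sided p for slope=0)."""
    values, age = values.align(age, join="inner")
    mask = values.notna() & age.notna()
    v, a = values[mask], age[mask]
    if a.nunique() < 2:
        raise CohortStatsError("age is constant: no trend estimable")
    if len(v) < 3:
        raise CohortStatsError("age trend requires at least 3 samples")
    res = sps.linregress(a.to_numpy(dtype=float), v.to_numpy(dtype=float))
    return float(res.slope), float(res.pvalue)


def top_correlated_genes(
    expr: pd.DataFrame, target: str, k: int = 100, method: str = "pearson"
) -> list[str]:
    """The k genes most correlated with ``target`` (target excluded).

    Ranking is by descending correlation; exact ties break lexicographically
    on the gene identifier, so the result is deterministic.
    """
    if target not in expr.columns:
        raise CohortStatsError(f"target gene {target!r} not in matrix")
    if k >= expr.shape[1]:
        raise CohortStatsError("k must be smaller than the number of genes")
    if k <= 0:
        return []
    validate_expression_matrix(expr)
    tvec = expr[target]
    if tvec.nunique() < 2:
        raise CohortStatsError(f"target gene {target!r} is constant")
    if method == "spearman":
        mat = expr.rank(axis=0)
        tv = tvec.rank()
    elif method == "pearson":
        mat, tv = expr, tvec
    else:
        raise CohortStatsError(f"unknown correlation method {method!r}")
    x = mat.to_numpy(dtype=float)
    t = tv.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pd.Series(xc.T @ tc / denom, index=mat.columns)
    corr = corr.drop(index=target).dropna()
    order = sorted(corr.index, key=lambda g: (-corr[g], g))
    return order[:k]


def enrichment_fisher(
    hits: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``hits`` against each gene set.

    For each set the 2×2 table is (hit∩set, hit∖set, set∖hit, remainder of the
    universe); the p-value is the upper hypergeometric tail (enrichment only).
    Returns a DataFrame indexed by set name, sorted by ascending p.
    """
    hit_set = set(hits)
    if not hit_set:
        raise CohortStatsError("empty hit list")
    uni = set(collection.universe)
    stray = hit_set - uni
    if stray:
        raise CohortStatsError(
            f"{len(stray)} hit genes outside the universe, e.g. {sorted(stray)[:3]}"
        )
    rows = []
    for name, genes in collection.sets.items():
        gs = set(genes)
        a = len(hit_set & gs)
        b = len(hit_set - gs)
        c = len(gs - hit_set)
        d = len(uni) - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, b, c, d, float(p)))
    out = pd.DataFrame(
        rows, columns=["set", "hit_in_set", "hit_out_set", "set_only", "rest", "p"]
    ).set_index("set")
    return out.sort_values(["p", "set"], kind="stable")


# -- I/O ---------------------------------------------------------------------


def read_gmt(path: str | Path, universe: Sequence[str]) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...; tab-separated)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise CohortStatsError(f"{path}: line {lineno}: malformed GMT line")
        sets[fields[0]] = fields[2:]
    return GeneSetCollection(sets=sets, universe=list(universe))


def read_metagenes_yaml(path: str | Path) -> list[MetageneDefinition]:
    """Read metagene definitions from YAML: ``{name: [marker, ...], ...}``."""
    payload = yaml.safe_load(Path(path).read_text())
    return [
        MetageneDefinition(name=name, markers=tuple(markers))
        for name, markers in payload.items()
    ]


def example_metagenes() -> list[MetageneDefinition]:
    """The packaged example marker lists (immune/stromal populations, Th cytokines)."""
    from importlib import resources

    with resources.as_file(
        resources.files("ighquant") / "data" / "metagenes.yaml"
    ) as path:
        return read_metagenes_yaml(path)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samples × genes TSV (first column sample id, '#' comments skipped)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_expression_tsv(expr: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        expr.to_csv(fh, sep="\t")
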