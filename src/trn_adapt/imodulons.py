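"""ICA data model and the basal iModulon activity transformation.

Independent component analysis factors a log-scale expression compendium
``X`` (genes x samples) into ``M @ A``: columns of ``M`` are iModulons
(independently modulated gene sets, each linked to a regulator) and rows of
``A`` are their activities across samples.  The raw sign convention of an
ICA component is arbitrary, so a high raw activity can mean either more or
less regulation.

The basal transformation fixes this.  Each iModulon gets a direction:

* ``-1`` — high raw activity already means high regulatory activity; the
  5th percentile of the raw activity over a reference compendium is
  subtracted, putting "no activity" near zero.
* ``+1`` — high raw activity means NO activity (a knockout of the linked
  regulator sits at the high end); the activity is reflected around its
  95th reference percentile and the corresponding ``M`` column is negated,
  so the product ``M @ A`` keeps predicting the same expression shifts.

After the transform, zero approximates "regulator not acting" and larger
values mean more regulatory activity, with at most ~5% of reference
samples below zero (the quantile tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from trn_adapt.errors import InvalidSpecError

SAMPLE_COLUMNS = ("strain", "lineage", "stage", "is_reference", "is_wildtype")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values (genes x samples) plus sample annotations.

    ``samples`` is indexed by sample id and may carry strain / lineage /
    stage / is_reference / is_wildtype columns; absent columns are filled
    with defaults.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise InvalidSpecError("gene and sample ids must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InvalidSpecError("expression values must be finite")
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        for col, default in (
            ("strain", ""),
            ("lineage", ""),
            ("stage", ""),
            ("is_reference", False),
            ("is_wildtype", False),
        ):
            if col not in self.samples.columns:
                self.samples[col] = default

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def reference_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["is_reference"].astype(bool)])


@dataclass
class Decomposition:
    """An ICA decomposition: M (genes x iModulons), A (iModulons x samples).

    ``annotations`` is indexed by iModulon name with a ``regulator`` column
    and an optional ``annotated_direction`` column (+1/-1, NaN if unknown).
    """

    M: pd.DataFrame
    A: pd.DataFrame
    annotations: pd.DataFrame = None

    def __post_init__(self) -> None:
        if not self.M.columns.equals(self.A.index):
            raise InvalidSpecError("M columns and A rows must list the same iModulons")
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                {"regulator": [""] * self.M.shape[1]}, index=self.M.columns
            )

    @property
    def imodulons(self) -> pd.Index:
        return self.M.columns

    def regulator_of(self, imodulon: str) -> str:
        return self.annotations.loc[imodulon, "regulator"]

    def reconstruct(self) -> pd.DataFrame:
        return self.M @ self.A


@dataclass
class BasalActivity:
    """Direction-corrected, quantile-shifted activities: 0 ~ no activity."""

    A_basal: pd.DataFrame
    directions: dict
    offsets: dict
    reference_ids: list = field(default_factory=list)

    def activity(self, imodulon: str, sample_ids: Sequence[str]) -> pd.Series:
        return self.A_basal.loc[imodulon, list(sample_ids)]

    def invert(self) -> pd.DataFrame:
        """Recover the raw A matrix from the basal one (exact inverse)."""
        rows = {}
        for k in self.A_basal.index:
            d, off = self.directions[k], self.offsets[k]
            b = self.A_basal.loc[k]
            rows[k] = b + off if d == -1 else off - b
        return pd.DataFrame(rows).T.loc[self.A_basal.index, self.A_basal.columns]


def member_genes(
    m_column: pd.Series, threshold_rule: str = "mean+2sd"
) -> set[str]:
    """Genes whose |weight| exceeds the threshold rule's cutoff.

    Default rule: mean + 2*sd of the absolute weights of the column.
    An all-zero column yields the empty set with a warning.
    """
    w = m_column.abs()
    if (w == 0).all():
        warnings.warn(f"iModulon column {m_column.name!r} is all zero", stacklevel=2)
        return set()
    if threshold_rule == "mean+2sd":
        cutoff = w.mean() + 2 * w.std(ddof=0)
    else:
        raise InvalidSpecError(f"unknown threshold rule {threshold_rule!r}")
    return set(w.index[w > cutoff])


def explained_variance(
    x: ExpressionMatrix, d: Decomposition, imodulon: str, gene_set: Iterable[str]
) -> float:
    """R^2 of a single iModulon's rank-1 reconstruction of a gene set.

    Rows of the gene-set expression block and of the rank-1 reconstruction
    M[:, k] A[k, :] are centered per gene across samples before the
    Frobenius norms; R^2 = 1 - ||Xc - Rc||_F^2 / ||Xc||_F^2.  The value is
    at most 1 and may be negative when the component anti-predicts.
    """
    genes = list(gene_set)
    if not genes:
        raise InvalidSpecError("gene_set is empty")
    missing = set(genes) - set(x.genes)
    if missing:
        raise InvalidSpecError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    xg = x.values.loc[genes].to_numpy(dtype=float)
    xc = xg - xg.mean(axis=1, keepdims=True)
    m_k = d.M.loc[genes, imodulon].to_numpy(dtype=float)[:, None]
    a_k = d.A.loc[imodulon, x.sample_ids].to_numpy(dtype=float)[None, :]
    recon = m_k @ a_k
    rc = recon - recon.mean(axis=1, keepdims=True)
    denom = float(np.sum(xc**2))
    if denom == 0:
        return 1.0 if float(np.sum(rc**2)) == 0 else -np.inf
    return 1.0 - float(np.sum((xc - rc) ** 2)) / denom


def assign_direction(
    a_row: pd.Series,
    reference_ids: Sequence[str],
    ko_sample_ids: Sequence[str] | None = None,
    annotated_direction: int | None = None,
) -> int:
    """Orient one iModulon: does high raw activity mean more or less regulation?

    When knockout samples of the linked regulator are available they anchor
    the no-activity end: if their mean raw activity exceeds the reference
    median, high raw values mean NO activity (direction +1), otherwise -1.
    Without KO samples the annotated direction is returned verbatim.  A KO
    mean exactly at the reference median resolves to -1 with a warning.
    """
    if not len(reference_ids):
        raise InvalidSpecError("reference_ids is empty")
    if ko_sample_ids is not None and len(ko_sample_ids):
        ko_mean = float(a_row.loc[list(ko_sample_ids)].mean())
        ref_median = float(a_row.loc[list(reference_ids)].median())
        if ko_mean == ref_median:
            warnings.warn(
                f"KO activity of {a_row.name!r} at reference median; direction -1",
                stacklevel=2,
            )
            return -1
        return 1 if ko_mean > ref_median else -1
    if annotated_direction in (1, -1):
        return int(annotated_direction)
    raise InvalidSpecError(
        "neither KO samples nor an annotated direction was provided"
    )


def basal_transform(
    d: Decomposition,
    directions: Mapping[str, int],
    reference_ids: Sequence[str],
) -> tuple[Decomposition, BasalActivity]:
    """Apply the basal-activity transformation to a decomposition.

    Per iModulon k, with quantiles taken over reference samples only
    (linear interpolation between order statistics):

    * direction -1: offset = 5th percentile; A'_k = A_k - offset; M
      column unchanged.
    * direction +1: offset = 95th percentile; A'_k = offset - A_k
      (shift, then sign flip); M column negated.

    The returned decomposition carries the transformed matrices; the
    BasalActivity records directions and offsets so the transform is
    exactly invertible.
    """
    refs = list(reference_ids)
    if not refs:
        raise InvalidSpecError("reference_ids is empty")
    missing = set(d.imodulons) - set(directions)
    if missing:
        raise InvalidSpecError(f"missing directions for iModulons: {sorted(missing)[:5]}")
    if len(refs) < 20:
        warnings.warn(
            f"only {len(refs)} reference samples; quantile offsets may be unstable",
            stacklevel=2,
        )
    a_new = d.A.copy().astype(float)
    m_new = d.M.copy().astype(float)
    offsets: dict = {}
    dirs: dict = {}
    for k in d.imodulons:
        direction = int(directions[k])
        if direction not in (1, -1):
            raise InvalidSpecError(f"direction for {k!r} must be +1 or -1")
        row = d.A.loc[k, refs].to_numpy(dtype=float)
        if direction == -1:
            offset = float(np.quantile(row, 0.05))
            a_new.loc[k] = d.A.loc[k] - offset
        else:
            offset = float(np.quantile(row, 0.95))
            a_new.loc[k] = offset - d.A.loc[k]
            m_new[k] = -m_new[k]
        offsets[k] = offset
        dirs[k] = direction
    d_new = Decomposition(M=m_new, A=a_new, annotations=d.annotations.copy())
    basal = BasalActivity(
        A_basal=a_new.copy(), directions=dirs, offsets=offsets, reference_ids=refs
    )
    return d_new, basal


def match_imodulons(
    d1: Decomposition, d2: Decomposition, r_threshold: float = 0.6
) -> tuple[pd.DataFrame, float]:
    """Match iModulons of two decompositions by gene-weight correlation.

    Pearson correlation of M columns over the shared gene universe; greedy
    one-to-one matching by descending |r|; a pair is reported matched when
    |r| >= ``r_threshold`` (sign-invariant, since ICA component signs are
    arbitrary).  Returns the (k1, k2, r, matched) table and the matched
    fraction relative to the smaller decomposition.
    """
    shared = d1.M.index.intersection(d2.M.index)
    if len(shared) < 10:
        raise InvalidSpecError(
            f"only {len(shared)} shared genes; need >= 10 for correlation matching"
        )
    m1 = d1.M.loc[shared].to_numpy(dtype=float)
    m2 = d2.M.loc[shared].to_numpy(dtype=float)
    c1 = m1 - m1.mean(axis=0)
    c2 = m2 - m2.mean(axis=0)
    denom = np.outer(np.linalg.norm(c1, axis=0), np.linalg.norm(c2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (c1.T @ c2) / denom, 0.0)
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(corr), axis=None), corr.shape))[0]
    used1: set[int] = set()
    used2: set[int] = set()
    rows = []
    for i, j in order:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        r = float(corr[i, j])
        rows.append(
            {
                "imodulon_1": d1.imodulons[i],
                "imodulon_2": d2.imodulons[j],
                "r": r,
                "matched": abs(r) >= r_threshold,
            }
        )
        if len(used1) == min(corr.shape):
            break
    table = pd.DataFrame(rows)
    matched_fraction = float(table["matched"].mean()) if len(table) else 0.0
    return table, matched_fraction


def differential_activity(
    b: BasalActivity,
    group1: Sequence[str],
    group2: Sequence[str],
    delta_threshold: float = 5.0,
    n_permutations: int = 10_000,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag iModulons whose basal activity differs between two sample groups.

    Per iModulon: delta = |mean(group1) - mean(group2)|, a two-sample
    permutation p-value by label shuffling, Benjamini-Hochberg correction
    across iModulons; flagged iff delta > ``delta_threshold`` (basal-scale
    units) AND q < ``fdr``.  This is a deliberately simple, fully
    specified test; it is not a calibrated noise model of ICA activities.
    """
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise InvalidSpecError("both groups must be nonempty")
    if set(g1) & set(g2):
        raise InvalidSpecError("groups overlap")
    rng = np.random.default_rng(seed)
    vals = b.A_basal[g1 + g2].to_numpy(dtype=float)
    n1 = len(g1)
    obs = np.abs(vals[:, :n1].mean(axis=1) - vals[:, n1:].mean(axis=1))
    exceed = np.zeros(vals.shape[0])
    for _ in range(n_permutations):
        perm = rng.permutation(vals.shape[1])
        shuffled = vals[:, perm]
        delta = np.abs(shuffled[:, :n1].mean(axis=1) - shuffled[:, n1:].mean(axis=1))
        exceed += delta >= obs
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "imodulon": b.A_basal.index,
            "delta": obs,
            "pvalue": pvals,
            "qvalue": qvals,
            "flagged": (obs > delta_threshold) & (qvals < fdr),
        }
    ).set_index("imodulon")


def diff_expressed_operons(
    x: ExpressionMatrix,
    operon_map: Mapping[str, str],
    cond_a: Sequence[str],
    cond_b: Sequence[str],
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed operons (DEO) between two conditions.

    Gene log2 fold change = mean over cond_a replicates minus mean over
    cond_b (the input is log scale); operon log2FC = mean over member
    genes.  The per-operon test pools member-gene replicate values (each
    gene centered by its grand mean across both conditions, so baselines
    cancel) into a two-sample t-test, BH-adjusted across operons.  An
    operon is DE iff |log2FC| > ``lfc_threshold`` and q < ``fdr``.
    """
    a, bb = list(cond_a), list(cond_b)
    if len(a) < 2 or len(bb) < 2:
        raise InvalidSpecError("need >= 2 replicates per condition")
    by_operon: dict[str, list[str]] = {}
    for gene, operon in operon_map.items():
        by_operon.setdefault(operon, []).append(gene)
    rows = []
    for operon, genes in sorted(by_operon.items()):
        measured = [g for g in genes if g in x.genes]
        if not measured:
            warnings.warn(f"operon {operon!r} has no measured genes; skipped", stacklevel=2)
            continue
        block_a = x.values.loc[measured, a].to_numpy(dtype=float)
        block_b = x.values.loc[measured, bb].to_numpy(dtype=float)
        gene_lfc = block_a.mean(axis=1) - block_b.mean(axis=1)
        lfc = float(gene_lfc.mean())
        grand = np.concatenate([block_a, block_b], axis=1).mean(axis=1, keepdims=True)
        ta = (block_a - grand).ravel()
        tb = (block_b - grand).ravel()
        tstat, pval = stats.ttest_ind(ta, tb)
        rows.append({"operon": operon, "n_genes": len(measured), "log2fc": lfc,
                     "tstat": float(tstat), "pvalue": float(pval)})
    table = pd.DataFrame(rows).set_index("operon")
    if len(table):
        _, qvals, _, _ = multipletests(table["pvalue"], method="fdr_bh")
        table["qvalue"] = qvals
        table["de"] = (table["log2fc"].abs() > lfc_threshold) & (table["qvalue"] < fdr)
    return table


# ---------------------------------------------------------------------------
# CSV dialects

def read_decomposition(
    m_path: str | Path, a_path: str | Path, annotations_path: str | Path | None = None
) -> Decomposition:
    """Read M / A / annotation CSVs (ids in the first row and column)."""
    m = pd.read_csv(m_path, index_col=0)
    a = pd.read_csv(a_path, index_col=0)
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, index_col=0)
    return Decomposition(M=m, A=a, annotations=ann)


def write_decomposition(d: Decomposition, m_path: str | Path, a_path: str | Path,
                        annotations_path: str | Path | None = None) -> None:
    d.M.to_csv(m_path)
    d.A.to_csv(a_path)
    if annotations_path is not None:
        d.annotations.to_csv(annotations_path)


def read_expression(values_path: str | Path, samples_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression TSV (genes x samples) and optional sample-metadata CSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, index_col=0) if samples_path else None
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(x: ExpressionMatrix, values_path: str | Path,
                     samples_path: str | Path | None = None) -> None:
    x.values.to_csv(values_path, sep="\t")
    if samples_path is not None:
        x.samples.to_csv(samples_path)
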