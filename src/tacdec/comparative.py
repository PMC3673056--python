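"""Phylogenetic comparative machinery: contrasts and lambda = 1 PGLS.

The cross-species prediction of the deception game is a positive association
between how often a species is recorded using tactical deception and how many
cooperative behaviours it engages in, controlling for cognitive capacity and
for research effort. The regression machinery here is phylogenetic
generalized least squares (PGLS) with the error covariance fixed at the
Brownian-motion expectation (Pagel's lambda = 1), which is numerically
equivalent to a through-origin regression on Felsenstein's independent
contrasts; both routes are implemented and can be checked against each other.

Two model structures are provided:

* ``ratio_model``:  log(deception + 1) ~ cooperativeness + neocortex ratio
  + log(research effort)
* ``volume_model``: log(deception + 1) ~ cooperativeness
  + log(neocortex volume) + log(research effort)

Natural logarithms are used throughout (significance is base-invariant;
coefficients scale with the base).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import GLS, OLS

__all__ = [
    "PhylogenyError",
    "TraitError",
    "RankError",
    "MODEL_STRUCTURES",
    "ContrastSet",
    "PGLSFit",
    "read_newick",
    "write_newick",
    "tree_from_string",
    "is_bifurcating",
    "resolve_polytomies",
    "prune_to_taxa",
    "canonical_name",
    "transform_traits",
    "independent_contrasts",
    "contrasts_matrix",
    "phylo_vcv",
    "pgls_fit",
    "contrasts_regression",
    "partial_out_contrasts",
    "compare_to_reference",
]


class PhylogenyError(ValueError):
    """Tree violates the requirements of the comparative analysis."""


class TraitError(ValueError):
    """Trait table violates the requirements of the comparative analysis."""


class RankError(ValueError):
    """The design matrix is rank deficient (e.g. a constant predictor)."""


#: response + predictor columns of the two supported model structures
MODEL_STRUCTURES = {
    "ratio_model": ["cooperativeness", "neocortex_ratio", "log_research_effort"],
    "volume_model": ["cooperativeness", "log_neocortex_volume", "log_research_effort"],
}
RESPONSE = "log_deception"


def canonical_name(name: str) -> str:
    """Canonical species key: underscores become spaces, case folded."""
    return " ".join(name.strip().replace("_", " ").split()).casefold()


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise PhylogenyError("tree must have at least 2 tips")
    canon = [canonical_name(l) for l in labels]
    if len(set(canon)) != len(canon):
        dupes = sorted({c for c in canon if canon.count(c) > 1})
        raise PhylogenyError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise PhylogenyError(
                f"missing branch length above node {node.taxon.label if node.taxon else node}"
            )
        if node.edge.length < 0:
            raise PhylogenyError(f"negative branch length {node.edge.length}")


def read_newick(path: str) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Trees flagged unrooted (``[&U]``) are rejected; trees without a rooting
    token are treated as rooted at the basal node. Polytomies are accepted
    (see :func:`is_bifurcating` / :func:`resolve_polytomies`).
    """
    return _parse_newick(path=path)


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    return _parse_newick(data=newick)


def _parse_newick(**source) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            rooting="default-rooted",
            **source,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"could not parse Newick input: {exc}") from exc
    if not tree.is_rooted:
        raise PhylogenyError("tree is explicitly unrooted ([&U]); a root is required")
    _validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    from .io import atomic_write

    atomic_write(path, tree.as_string(schema="newick", unquoted_underscores=True))


def is_bifurcating(tree: dendropy.Tree) -> bool:
    """True when every internal node (incl. the root) has exactly 2 children."""
    return all(
        len(node.child_nodes()) == 2
        for node in tree.preorder_internal_node_iter()
    )


def resolve_polytomies(tree: dendropy.Tree, seed: int | None = None) -> dendropy.Tree:
    """Return a copy with polytomies arbitrarily resolved by zero-length edges.

    Consensus trees often contain polytomies; resolving with zero-length
    internal edges leaves all tip-to-tip path lengths unchanged, so contrasts
    and PGLS results do not depend on the (seedable) resolution order.
    """
    out = tree.clone(depth=1)
    rng = random.Random(seed) if seed is not None else None
    out.resolve_polytomies(rng=rng)
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return out


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Copy of ``tree`` restricted to ``taxa`` (path lengths preserved).

    Species names are matched after canonicalization (underscores/spaces,
    case). Unknown taxa raise with the full list of offenders; pruning to
    fewer than 2 tips is refused (no contrasts are possible).
    """
    wanted = {canonical_name(t) for t in taxa}
    if len(wanted) < 2:
        raise PhylogenyError("cannot prune to fewer than 2 taxa")
    by_canon = {
        canonical_name(leaf.taxon.label): leaf.taxon.label
        for leaf in tree.leaf_node_iter()
    }
    unknown = sorted(wanted - set(by_canon))
    if unknown:
        raise PhylogenyError(f"taxa not in tree: {unknown}")
    out = tree.clone(depth=1)
    out.retain_taxa_with_labels([by_canon[c] for c in wanted])
    return out


def transform_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the analysis transforms to a validated trait table.

    Adds ``log_deception = ln(deception_count + 1)``,
    ``log_research_effort = ln(research_effort)`` and
    ``log_neocortex_volume = ln(neocortex_volume)``; cooperativeness and
    neocortex ratio enter untransformed.
    """
    out = table.copy()
    if (out["deception_count"] < 0).any():
        raise TraitError("deception_count must be non-negative")
    for col in ("research_effort", "neocortex_volume"):
        if col in out.columns and (out[col] <= 0).any():
            bad = out.index[out[col] <= 0].tolist()
            raise TraitError(f"{col} must be positive (rows {bad})")
    out[RESPONSE] = np.log1p(out["deception_count"].astype(float))
    out["log_research_effort"] = np.log(out["research_effort"].astype(float))
    if "neocortex_volume" in out.columns:
        out["log_neocortex_volume"] = np.log(out["neocortex_volume"].astype(float))
    return out


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts at the internal nodes of a tree.

    ``contrasts`` is indexed by node id with one column per trait;
    ``variances`` holds each node's expected contrast variance (the sum of
    its daughters' rate-adjusted branch lengths). On a fully bifurcating
    tree there are ``n_tips - 1`` contrasts.
    """

    contrasts: pd.DataFrame
    variances: pd.Series


def _contrasts_engine(
    tree: dendropy.Tree, values: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Felsenstein pruning for one or more traits simultaneously.

    At each internal node the contrast is the difference of the two daughter
    values divided by sqrt(v1 + v2), where v_i is the daughter's branch
    length plus its pruning correction; the node's ancestral value is the
    inverse-variance-weighted daughter mean and its own parent branch is
    lengthened by v1 v2 / (v1 + v2).
    """
    work = tree.clone(depth=1)
    if not is_bifurcating(work):
        raise PhylogenyError(
            "tree has polytomies; resolve them first (resolve_polytomies)"
        )
    cols = list(values.columns)
    by_canon = {canonical_name(i): i for i in values.index}
    rows: list[dict] = []
    variances: dict[str, float] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            key = canonical_name(node.taxon.label)
            if key not in by_canon:
                raise TraitError(f"no trait value for tip {node.taxon.label!r}")
            node._ic_values = values.loc[by_canon[key], cols].to_numpy(dtype=float)
            node._ic_extra = 0.0
            continue
        left, right = node.child_nodes()
        v1 = left.edge.length + left._ic_extra
        v2 = right.edge.length + right._ic_extra
        total = v1 + v2
        node_id = f"node{len(rows)}"
        if total <= 0:
            raise PhylogenyError(
                f"zero total daughter branch length at internal node {node_id}"
            )
        contrast = (left._ic_values - right._ic_values) / np.sqrt(total)
        rows.append(dict(zip(cols, contrast), node=node_id))
        variances[node_id] = total
        node._ic_values = (v2 * left._ic_values + v1 * right._ic_values) / total
        node._ic_extra = v1 * v2 / total
    frame = pd.DataFrame(rows).set_index("node")
    return frame[cols], pd.Series(variances, name="variance")


def independent_contrasts(tree: dendropy.Tree, trait) -> ContrastSet:
    """Standardized independent contrasts of one trait (or several columns).

    ``trait`` is a mapping/Series of tip label -> value, or a DataFrame with
    one column per trait. The tree must be bifurcating.
    """
    if isinstance(trait, pd.DataFrame):
        values = trait
    else:
        values = pd.Series(dict(trait), name="trait").to_frame()
    contrasts, variances = _contrasts_engine(tree, values)
    return ContrastSet(contrasts=contrasts, variances=variances)


def contrasts_matrix(tree: dendropy.Tree, table: pd.DataFrame, columns) -> pd.DataFrame:
    """Contrasts of several columns computed in one shared traversal."""
    return _contrasts_engine(tree, table[list(columns)])[0]


def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    Returns tip labels (tree leaf order) and the matrix C with
    C[i, i] = root-to-tip distance and C[i, j] = depth of the most recent
    common ancestor of tips i and j.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # accumulate depths top-down, then fill pair entries at each MRCA
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        edge = node.edge.length or 0.0
        node._depth = parent_depth + edge
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = node._depth
            node._tips = [i]
            continue
        kids = node.child_nodes()
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]._tips:
                    for j in kids[b]._tips:
                        C[i, j] = C[j, i] = node._depth
        node._tips = [i for k in kids for i in k._tips]
    return labels, C


@dataclass(frozen=True)
class PGLSFit:
    """A fitted phylogenetic regression at lambda = 1.

    ``params``/``bse``/``tvalues``/``pvalues`` are indexed by term
    (including ``intercept`` for the GLS route). p-values are two-sided from
    the t distribution on ``df_resid = n - k`` degrees of freedom.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    nobs: int
    model: str
    sigma2: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _align(tree: dendropy.Tree, table: pd.DataFrame) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Prune tree to the table's species and order rows to tree leaf order."""
    if "species" in table.columns:
        table = table.set_index("species")
    sub = prune_to_taxa(tree, list(table.index))
    labels = [leaf.taxon.label for leaf in sub.leaf_node_iter()]
    by_canon = {canonical_name(i): i for i in table.index}
    ordered = table.loc[[by_canon[canonical_name(l)] for l in labels]]
    ordered.index = labels
    return sub, ordered


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError(
            f"design matrix is rank deficient (terms: {list(names)}); "
            "a predictor may be constant or collinear"
        )


def pgls_fit(
    tree: dendropy.Tree, table: pd.DataFrame, model: str = "ratio_model"
) -> PGLSFit:
    """Fit one of the two model structures by GLS with Brownian covariance.

    The response is ln(deception count + 1); the error covariance is
    proportional to the shared-path-length matrix of the pruned tree
    (lambda = 1 exactly, no signal estimation). An intercept is estimated;
    standard errors, t statistics and two-sided p-values are on
    n - k residual degrees of freedom.
    """
    if model not in MODEL_STRUCTURES:
        raise ValueError(f"model must be one of {sorted(MODEL_STRUCTURES)}")
    predictors = MODEL_STRUCTURES[model]
    sub, data = _align(tree, transform_traits(table))
    return _gls_on_tree(sub, data, RESPONSE, predictors, model_name=model)


def _gls_on_tree(
    tree: dendropy.Tree,
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    model_name: str = "custom",
) -> PGLSFit:
    labels, C = phylo_vcv(tree)
    data = data.loc[labels]
    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(labels))] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["intercept"] + predictors
    if len(y) < X.shape[1] + 1:
        raise TraitError(
            f"need at least {X.shape[1] + 1} species for {len(predictors)} "
            f"predictors, got {len(y)}"
        )
    _check_rank(X, names)
    res = GLS(y, X, sigma=C).fit()
    idx = pd.Index(names)
    return PGLSFit(
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        df_resid=int(res.df_resid),
        nobs=len(y),
        model=model_name,
        sigma2=float(res.scale),
    )


def contrasts_regression(
    tree: dendropy.Tree,
    table: pd.DataFrame,
    response: str = RESPONSE,
    predictors: list[str] | None = None,
    model: str | None = "ratio_model",
) -> PGLSFit:
    """Through-origin regression on independent contrasts.

    Numerically equivalent to :func:`pgls_fit` at lambda = 1 for the slope
    terms (there is no intercept analogue); kept as an independent route so
    the two implementations can be cross-checked.
    """
    if predictors is None:
        predictors = MODEL_STRUCTURES[model]
    sub, data = _align(tree, transform_traits(table))
    if not is_bifurcating(sub):
        sub = resolve_polytomies(sub, seed=0)
    contrasts = contrasts_matrix(sub, data, [response] + list(predictors))
    y = contrasts[response].to_numpy()
    X = contrasts[list(predictors)].to_numpy()
    _check_rank(X, predictors)
    res = OLS(y, X).fit()
    idx = pd.Index(predictors)
    return PGLSFit(
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        df_resid=int(res.df_resid),
        nobs=len(y) + 1,
        model=f"contrasts:{model or 'custom'}",
        sigma2=float(res.scale),
    )


def partial_out_contrasts(
    tree: dendropy.Tree,
    table: pd.DataFrame,
    focal: str,
    nuisances: list[str],
    response: str = RESPONSE,
) -> pd.DataFrame:
    """Residual contrasts of response and focal predictor, nuisances removed.

    Both the response contrasts and the focal-predictor contrasts are
    residualised by a through-origin regression on the nuisance contrasts;
    by the Frisch-Waugh-Lovell theorem the through-origin slope of the
    returned (x, y) pairs equals the focal coefficient of the full
    contrasts/PGLS fit. With an empty nuisance set the raw contrasts are
    returned. Columns: node, x (focal), y (response).
    """
    sub, data = _align(tree, transform_traits(table))
    if not is_bifurcating(sub):
        sub = resolve_polytomies(sub, seed=0)
    cols = [response, focal] + list(nuisances)
    contrasts = contrasts_matrix(sub, data, cols)
    y = contrasts[response].to_numpy()
    x = contrasts[focal].to_numpy()
    if nuisances:
        Z = contrasts[list(nuisances)].to_numpy()
        _check_rank(Z, nuisances)
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    return pd.DataFrame({"node": contrasts.index, "x": x, "y": y}).set_index("node")


def compare_to_reference(
    tree: dendropy.Tree,
    table: pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Run both model structures and tabulate against reference coefficients.

    ``reference`` has columns (model, term, beta, se, p); useful for checking
    a user-supplied species table and phylogeny against previously published
    estimates. Returns the reference rows with fitted values and differences
    appended.
    """
    fits = {m: pgls_fit(tree, table, model=m) for m in MODEL_STRUCTURES}
    rows = []
    for _, row in reference.iterrows():
        fit = fits[row["model"]]
        term = row["term"]
        rows.append(
            {
                **row,
                "beta_fit": fit.params.get(term, np.nan),
                "se_fit": fit.bse.get(term, np.nan),
                "p_fit": fit.pvalues.get(term, np.nan),
                "beta_diff": fit.params.get(term, np.nan) - row["beta"],
            }
        )
    return pd.DataFrame(rows)
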