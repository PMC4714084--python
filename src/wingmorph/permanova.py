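"""Permutational multivariate ANOVA on Euclidean distances.

For Euclidean distances the PERMANOVA sums of squares coincide with the
classical multivariate ANOVA partition of the centred feature matrix
(Gower's identity), so SS are computed directly in feature space — never
through an explicit n×n distance matrix. Balanced crossed/nested mixed
designs are supported: each term's SS comes from the sums of squares of
its cell means with the SS of every contained (coarser) term subtracted,
which reproduces the textbook balanced-ANOVA decomposition; degrees of
freedom follow the same inclusion–exclusion.

Pseudo-F denominators default to the residual mean square. An
EMS-based selection (restricted-model rules: the denominator of a term is
the minimal random term containing it whose extra factors are all random)
is available with ``denominator='ems'``; terms with no unique EMS
denominator are flagged quasi-F and fall back to the residual with a
caveat. p-values are permutation probabilities from unrestricted row
permutations, with the observed statistic included in both numerator and
denominator: p = (#{F* ≥ F} + 1)/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


class UnbalancedDesignError(ValueError):
    """The design requires equal cell counts and the data are not balanced."""


@dataclass(frozen=True)
class Factor:
    name: str
    kind: str = "fixed"  # 'fixed' | 'random'
    nested_in: tuple = ()

    def __post_init__(self):
        if self.kind not in ("fixed", "random"):
            raise ValueError(f"factor kind must be fixed|random, got {self.kind!r}")


@dataclass(frozen=True)
class Term:
    """One tested effect: the factors explicitly crossed in the term."""

    factors: tuple  # explicit factor names, e.g. ('sex', 'image')

    def label(self, design: "Design") -> str:
        parts = []
        for f in self.factors:
            parents = design.factors[f].nested_in
            parts.append(f"{f}({'*'.join(parents)})" if parents else f)
        return ":".join(parts)


@dataclass
class Design:
    """A declared ANOVA design: factors (fixed/random, nesting) and terms."""

    factors: dict  # name -> Factor
    terms: list  # list of Term

    def __post_init__(self):
        # nesting graph must be acyclic and refer to declared factors
        for f in self.factors.values():
            seen = set()
            stack = list(f.nested_in)
            while stack:
                parent = stack.pop()
                if parent not in self.factors:
                    raise ValueError(f"factor {f.name} nested in unknown {parent!r}")
                if parent == f.name:
                    raise ValueError(f"cyclic nesting through {parent!r}")
                if parent in seen:  # diamond, already expanded
                    continue
                seen.add(parent)
                stack.extend(self.factors[parent].nested_in)
        for t in self.terms:
            for f in t.factors:
                if f not in self.factors:
                    raise ValueError(f"term uses undeclared factor {f!r}")

    # -- structure helpers ---------------------------------------------------

    def ancestors(self, name: str) -> frozenset:
        out = set()
        stack = list(self.factors[name].nested_in)
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.factors[p].nested_in)
        return frozenset(out)

    def full_set(self, term: Term) -> frozenset:
        """All factors indexing the term's cells (explicit + nesting parents)."""
        out = set()
        for f in term.factors:
            out.add(f)
            out |= self.ancestors(f)
        return frozenset(out)

    def is_random(self, term: Term) -> bool:
        return any(self.factors[f].kind == "random" for f in self.full_set(term))

    @classmethod
    def from_formula(cls, formula: str, random: Sequence[str] = ()) -> "Design":
        """Parse ``'sex + wing + image(wing) + sex:image(wing)'``.

        Terms are separated by ``+``; crossed components within a term by
        ``:``; nesting parents in parentheses, ``*``-separated. Factors in
        ``random`` are random, all others fixed.
        """
        random = set(random)
        factors: dict[str, Factor] = {}
        terms: list[Term] = []
        for raw_term in formula.split("+"):
            raw_term = raw_term.strip()
            if not raw_term:
                continue
            names = []
            for comp in raw_term.split(":"):
                comp = comp.strip()
                if "(" in comp:
                    name, _, rest = comp.partition("(")
                    if not rest.endswith(")"):
                        raise ValueError(f"malformed term component {comp!r}")
                    parents = tuple(
                        p.strip() for p in rest[:-1].replace("*", ",").split(",") if p.strip()
                    )
                else:
                    name, parents = comp, ()
                name = name.strip()
                if name in factors:
                    if parents and factors[name].nested_in != parents:
                        raise ValueError(f"factor {name} declared with two nestings")
                else:
                    factors[name] = Factor(
                        name, "random" if name in random else "fixed", parents
                    )
                names.append(name)
            terms.append(Term(tuple(names)))
        unknown = random - set(factors)
        if unknown:
            raise ValueError(f"random factors not in formula: {sorted(unknown)}")
        return cls(factors=factors, terms=terms)


def one_way_design(factor: str = "group") -> Design:
    return Design(factors={factor: Factor(factor, "fixed")}, terms=[Term((factor,))])


# ---------------------------------------------------------------------------
# degrees of freedom
# ---------------------------------------------------------------------------


def _mobius_df(design: Design, n_combos: dict) -> dict:
    """df per term by inclusion–exclusion over full factor sets."""
    fulls = {t: design.full_set(t) for t in design.terms}
    df: dict[Term, int] = {}
    for t in sorted(design.terms, key=lambda t: len(fulls[t])):
        contained = sum(df[u] for u in df if fulls[u] < fulls[t])
        df[t] = n_combos[fulls[t]] - 1 - contained
        if df[t] < 1:
            raise ValueError(f"term {t.label(design)} has non-positive df {df[t]}")
    return df


def design_df(design: Design, level_counts: dict, replicates: int) -> dict:
    """Degrees of freedom per term plus the residual for a balanced design.

    ``level_counts[f]`` is the number of levels of factor ``f`` *within
    each combination of its nesting parents*; ``replicates`` is the
    number of observations per finest cell (all declared factors crossed).
    """
    if replicates < 1 or any(v < 1 for v in level_counts.values()):
        raise ValueError("level counts and replicates must be ≥ 1")
    missing = set(design.factors) - set(level_counts)
    if missing:
        raise ValueError(f"level_counts missing factors: {sorted(missing)}")
    n_combos = {}
    for t in design.terms:
        fs = design.full_set(t)
        n_combos[fs] = int(np.prod([level_counts[f] for f in fs]))
    n_total = replicates * int(np.prod([level_counts[f] for f in design.factors]))
    df = _mobius_df(design, n_combos)
    out = {t.label(design): df[t] for t in design.terms}
    resid = n_total - 1 - sum(df.values())
    if resid < 0:
        raise ValueError("design over-parameterized: negative residual df")
    out["Residual"] = resid
    return out


# ---------------------------------------------------------------------------
# EMS denominator selection
# ---------------------------------------------------------------------------


def _select_denominators(design: Design) -> dict:
    """term -> (denominator term | 'Residual', quasi_f_flag).

    Restricted-model rule: candidate denominators for T are random terms U
    with full(T) ⊊ full(U) whose extra factors full(U)∖full(T) are all
    random; the unique minimal candidate wins. No candidate → residual.
    Several minimal candidates → quasi-F: warn, use residual, flag.
    """
    fulls = {t: design.full_set(t) for t in design.terms}
    out = {}
    for t in design.terms:
        candidates = [
            u
            for u in design.terms
            if u is not t
            and fulls[t] < fulls[u]
            and design.is_random(u)
            and all(design.factors[f].kind == "random" for f in fulls[u] - fulls[t])
        ]
        minimal = [
            u for u in candidates if not any(fulls[v] < fulls[u] for v in candidates)
        ]
        if not minimal:
            out[t] = ("Residual", False)
        elif len(minimal) == 1:
            out[t] = (minimal[0], False)
        else:
            warnings.warn(
                f"no unique EMS denominator for term {t.label(design)}; "
                "quasi-F situation, reporting residual-denominator F"
            )
            out[t] = ("Residual", True)
    return out


# ---------------------------------------------------------------------------
# sums of squares
# ---------------------------------------------------------------------------


def _cell_codes(metadata: pd.DataFrame, factors: Sequence[str]):
    """Integer cell code per row for a combination of factor columns."""
    codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(metadata[list(factors)].astype(str)), sort=True
    )
    return np.asarray(codes), int(codes.max()) + 1


def _batch_term_ss(
    x_batch: np.ndarray, order: np.ndarray, n_cells: int, correction: float
) -> np.ndarray:
    """S(F) for a batch of (possibly permuted) feature matrices.

    ``x_batch`` is (B, n, p); rows sorted by ``order`` fall into
    ``n_cells`` equal-sized cells. Returns (B,) sums of squares of cell
    means about the grand mean, summed over features.
    """
    b, n, p = x_batch.shape
    m = n // n_cells
    sums = x_batch[:, order, :].reshape(b, n_cells, m, p).sum(axis=2)
    return (sums**2).sum(axis=(1, 2)) / m - correction


def permanova(
    features: np.ndarray,
    design: Design,
    metadata: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    denominator: str = "residual",
    exact: bool = False,
) -> pd.DataFrame:
    """PERMANOVA table for a declared design.

    Parameters
    ----------
    features : (n, p) array
        Numeric response matrix; Euclidean geometry is assumed.
    design : Design
    metadata : DataFrame with one column per design factor, n rows
        aligned with ``features``.
    n_perm : int
        Number of unrestricted row permutations (0 → no p-values).
    denominator : {'residual', 'ems'}
        Mean-square denominator policy (see module docstring).
    exact : bool
        Enumerate all n! row permutations instead of sampling (small n
        only); p = #{F* ≥ F} / n!, the identity permutation included.

    Returns
    -------
    DataFrame with one row per term plus 'Residual' and 'Total';
    columns: df, SS, MS, F, denominator, p_perm, n_perm, quasi_f.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    n, p = features.shape
    if len(metadata) != n:
        raise ValueError("metadata rows must align with feature rows")
    if denominator not in ("residual", "ems"):
        raise ValueError("denominator must be 'residual' or 'ems'")

    fulls = {t: design.full_set(t) for t in design.terms}
    multi_factor = len(design.factors) > 1

    # cell structure per distinct full factor set
    cells = {}
    for fs in set(fulls.values()):
        codes, n_cells = _cell_codes(metadata, sorted(fs))
        counts = np.bincount(codes, minlength=n_cells)
        if multi_factor and len(set(counts)) != 1:
            raise UnbalancedDesignError(
                f"unequal cell counts for factors {sorted(fs)}: "
                f"{sorted(set(counts))}; use balanced_subsample first"
            )
        cells[fs] = (codes, n_cells, counts)

    total_colsum = features.sum(axis=0)
    correction = float((total_colsum**2).sum()) / n
    ss_total = float((features**2).sum()) - correction

    def raw_ss(x_batch: np.ndarray) -> dict:
        """S(F) per full set for a (B, n, p) batch."""
        out = {}
        for fs, (codes, n_cells, counts) in cells.items():
            if len(set(counts)) == 1:
                order = np.argsort(codes, kind="stable")
                out[fs] = _batch_term_ss(x_batch, order, n_cells, correction)
            else:  # unbalanced one-way: explicit per-cell division
                b = x_batch.shape[0]
                vals = np.zeros(b)
                for c in range(n_cells):
                    mask = codes == c
                    s = x_batch[:, mask, :].sum(axis=1)
                    vals += (s**2).sum(axis=1) / counts[c]
                out[fs] = vals - correction
        return out

    def partition(raw: dict) -> dict:
        """Möbius inversion: term SS from raw cell-mean SS."""
        ss = {}
        for t in sorted(design.terms, key=lambda t: len(fulls[t])):
            ss[t] = raw[fulls[t]] - sum(
                ss[u] for u in ss if fulls[u] < fulls[t]
            )
        return ss

    obs_ss = {t: float(v[0]) for t, v in partition(raw_ss(features[None])).items()}
    resid_ss = ss_total - sum(obs_ss.values())

    # degrees of freedom from the observed cell structure
    n_combos = {fs: cells[fs][1] for fs in cells}
    df = _mobius_df(design, n_combos)
    resid_df = n - 1 - sum(df.values())
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom")

    denom_map = (
        _select_denominators(design)
        if denominator == "ems"
        else {t: ("Residual", False) for t in design.terms}
    )

    def f_stats(ss: dict, rss: np.ndarray) -> dict:
        ms = {t: ss[t] / df[t] for t in design.terms}
        ms_resid = rss / resid_df
        out = {}
        for t in design.terms:
            d, _ = denom_map[t]
            denom_ms = ms_resid if d == "Residual" else ms[d]
            with np.errstate(divide="ignore", invalid="ignore"):
                out[t] = np.where(denom_ms > 0, ms[t] / denom_ms, np.inf)
        return out

    obs_f = {
        t: float(np.asarray(v).reshape(-1)[0])
        for t, v in f_stats(
            {t: np.asarray([s]) for t, s in obs_ss.items()}, np.asarray([resid_ss])
        ).items()
    }

    p_perm = {t: np.nan for t in design.terms}
    if exact:
        if n > 9:
            raise ValueError("exact enumeration is limited to n ≤ 9 rows")
        all_perms = np.array(list(itertools.permutations(range(n))))
        exceed = {t: 0 for t in design.terms}
        for start in range(0, len(all_perms), 5000):
            xb = features[all_perms[start : start + 5000]]
            ss_b = partition(raw_ss(xb))
            rss_b = ss_total - sum(ss_b.values())
            fb = f_stats(ss_b, rss_b)
            for t in design.terms:
                exceed[t] += int(np.sum(fb[t] >= obs_f[t] - 1e-12))
        n_perm = len(all_perms)
        p_perm = {t: exceed[t] / n_perm for t in design.terms}
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = {t: 0 for t in design.terms}
        batch = max(1, min(n_perm, int(2e7 // (n * p)) or 1))
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)  # b random row permutations
            xb = features[idx]
            ss_b = partition(raw_ss(xb))
            rss_b = ss_total - sum(ss_b.values())
            fb = f_stats(ss_b, rss_b)
            for t in design.terms:
                exceed[t] += int(np.sum(fb[t] >= obs_f[t] - 1e-12))
            done += b
        p_perm = {t: (exceed[t] + 1) / (n_perm + 1) for t in design.terms}

    rows = []
    for t in design.terms:
        d, quasi = denom_map[t]
        rows.append(
            {
                "term": t.label(design),
                "df": df[t],
                "SS": obs_ss[t],
                "MS": obs_ss[t] / df[t],
                "F": obs_f[t],
                "denominator": d if d == "Residual" else d.label(design),
                "p_perm": p_perm[t],
                "n_perm": n_perm,
                "quasi_f": quasi,
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": resid_df,
            "SS": resid_ss,
            "MS": resid_ss / resid_df,
            "F": np.nan,
            "denominator": "",
            "p_perm": np.nan,
            "n_perm": n_perm,
            "quasi_f": False,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "F": np.nan,
            "denominator": "",
            "p_perm": np.nan,
            "n_perm": n_perm,
            "quasi_f": False,
        }
    )
    return pd.DataFrame(rows).set_index("term")


def one_way_permanova(
    features: np.ndarray,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """One-way PERMANOVA; groups need not be balanced."""
    labels = np.asarray(labels, dtype=object).astype(str)
    meta = pd.DataFrame({"group": labels})
    return permanova(
        features, one_way_design("group"), meta, n_perm=n_perm, seed=seed, exact=exact
    )


# ---------------------------------------------------------------------------
# pairwise comparisons and FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def pairwise_tests(
    features: np.ndarray,
    group_labels,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise two-group PERMANOVA t-tests with FDR correction.

    t = √(pseudo-F) of the two-group one-way test; permutation p per
    pair; Benjamini–Hochberg adjusted p appended. Pairs where either
    group has < 2 replicates are flagged untestable (NaN statistics).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(group_labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        mask = (labels == a) | (labels == b)
        n_a, n_b = int(np.sum(labels == a)), int(np.sum(labels == b))
        if min(n_a, n_b) < 2:
            rows.append(
                {"group_1": a, "group_2": b, "t": np.nan, "p_perm": np.nan,
                 "testable": False}
            )
            continue
        table = one_way_permanova(
            features[mask], labels[mask], n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        f = table.loc["group", "F"]
        rows.append(
            {"group_1": a, "group_2": b, "t": float(np.sqrt(f)),
             "p_perm": float(table.loc["group", "p_perm"]), "testable": True}
        )
    out = pd.DataFrame(rows)
    testable = out["testable"] & out["p_perm"].notna()
    out["p_fdr"] = np.nan
    if testable.any():
        out.loc[testable, "p_fdr"] = fdr_adjust(out.loc[testable, "p_perm"].to_numpy())
    return out


def balanced_subsample(
    metadata: pd.DataFrame,
    group_factor: str,
    n_per_group: int,
    seed: int | None = None,
) -> list:
    """Sample exactly ``n_per_group`` specimen ids per group, without
    replacement, reproducibly by ``seed``.

    ``metadata`` is indexed by specimen_id (see
    :func:`wingmorph.data_model.metadata_frame`). Rows with missing group
    labels are ignored. Groups smaller than ``n_per_group`` are an error.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be ≥ 1")
    rng = np.random.default_rng(seed)
    valid = metadata[metadata[group_factor].notna()]
    ids: list = []
    for group, sub in sorted(valid.groupby(group_factor), key=lambda kv: str(kv[0])):
        if len(sub) < n_per_group:
            raise ValueError(
                f"group {group!r} has only {len(sub)} members, "
                f"needs {n_per_group}"
            )
        chosen = rng.choice(sub.index.to_numpy(), size=n_per_group, replace=False)
        ids.extend(chosen.tolist())
    return ids
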