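"""Grey-matter/white-matter coupling via random-intercept mixed models.

For every participant and region we summarise white matter as the mean
w-score of all retained, non-missing tracts incident to the region ("tracts
projecting from" the region; each tract counts toward both endpoints).
That summary is regressed on the regional grey-matter volume w-score with a
moderator (diagnostic group, phenotype, or APOE e4 copy number), the
moderator x GM interaction, and a random intercept per participant to absorb
within-subject correlation across the repeated regional measures.

Inference uses Wald F tests on the REML fit with Satterthwaite-approximated
denominator degrees of freedom.  For a random-intercept-only model the
marginal covariance is block diagonal, V_i = sigma^2 I + tau^2 11', so the
quantities the Satterthwaite approximation needs (X'V^-1X and its
derivatives with respect to the variance components, and the REML expected
information) all have closed per-participant forms; no n x n matrices are
ever built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import level_order
from .wscore import WScoreTable


# --------------------------------------------------------------------------
# region-level white-matter summary
# --------------------------------------------------------------------------

def summarize_region_wm(wtable: WScoreTable) -> pd.DataFrame:
    """Mean tract w-score per (participant, region), missing tracts excluded.

    Regions with zero usable tracts for a participant emit no row.
    """
    t = wtable.table.copy()
    parts = t["target_id"].str.partition("--")
    t["region_a"] = parts[0]
    t["region_b"] = parts[2]
    long = pd.concat([
        t[["participant_id", "region_a", "w"]].rename(
            columns={"region_a": "region"}),
        t[["participant_id", "region_b", "w"]].rename(
            columns={"region_b": "region"}),
    ], ignore_index=True)
    long = long[np.isfinite(long["w"])]
    out = (long.groupby(["participant_id", "region"], as_index=False)
           .agg(mean_wm_w=("w", "mean"), n_tracts_used=("w", "size")))
    return out.sort_values(["participant_id", "region"], ignore_index=True)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _build_design(
    df: pd.DataFrame,
    factors: Dict[str, List[str]],
    continuous: Sequence[str],
    interactions: Sequence[Tuple[str, ...]],
) -> "Design":
    """Treatment-coded design with intercept.

    Each non-intercept column is tagged with the variable/level combination
    it represents, and the factor level counts are retained, so that Type
    III contrasts (continuous covariates at zero, factors averaged with
    equal level weights) can be constructed for the ANOVA.
    """
    pieces: Dict[str, Tuple[np.ndarray, List[str], List[Dict[str, str]]]] = {}
    for var, levels in factors.items():
        cols = np.column_stack(
            [(df[var] == lev).astype(float) for lev in levels[1:]])
        pieces[var] = (cols, [f"{var}{lev}" for lev in levels[1:]],
                       [{var: lev} for lev in levels[1:]])
    for var in continuous:
        pieces[var] = (df[var].to_numpy(float)[:, None], [var], [{var: var}])

    X_cols = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    col_tags: List[Dict[str, str]] = [{}]
    term_cols: Dict[str, List[int]] = {}
    term_vars: Dict[str, Tuple[str, ...]] = {}
    col = 1
    for var in list(factors) + list(continuous):
        block, labels, tags = pieces[var]
        X_cols.append(block)
        names.extend(labels)
        col_tags.extend(tags)
        term_cols[var] = list(range(col, col + block.shape[1]))
        term_vars[var] = (var,)
        col += block.shape[1]
    for inter in interactions:
        blocks = [pieces[v] for v in inter]
        cur, cur_names, cur_tags = blocks[0]
        for blk, labels, tags in blocks[1:]:
            cur = np.concatenate(
                [cur[:, [i]] * blk for i in range(cur.shape[1])], axis=1)
            cur_names = [f"{a}:{b}" for a in cur_names for b in labels]
            cur_tags = [{**ta, **tb} for ta in cur_tags for tb in tags]
        X_cols.append(cur)
        names.extend(cur_names)
        col_tags.extend(cur_tags)
        term = ":".join(inter)
        term_cols[term] = list(range(col, col + cur.shape[1]))
        term_vars[term] = tuple(inter)
        col += cur.shape[1]
    return Design(X=np.concatenate(X_cols, axis=1), names=names,
                  term_cols=term_cols, term_vars=term_vars,
                  col_tags=col_tags,
                  factor_levels={v: len(l) for v, l in factors.items()},
                  continuous=list(continuous))


@dataclass
class Design:
    X: np.ndarray
    names: List[str]
    term_cols: Dict[str, List[int]]
    term_vars: Dict[str, Tuple[str, ...]]
    col_tags: List[Dict[str, str]]
    factor_levels: Dict[str, int]
    continuous: List[str]

    def type3_contrast(self, term: str) -> np.ndarray:
        """Type III contrast rows for a model term.

        Starting from identity rows on the term's own columns, every
        higher-order interaction containing the term contributes its
        matching columns averaged over the extra factor levels; extra
        continuous variables are held at zero (no contribution).
        """
        tvars = set(self.term_vars[term])
        rows = []
        for c in self.term_cols[term]:
            l = np.zeros(self.X.shape[1])
            l[c] = 1.0
            base = self.col_tags[c]
            for other, ovars in self.term_vars.items():
                oset = set(ovars)
                if other == term or not tvars < oset:
                    continue
                extra = oset - tvars
                if any(v in self.continuous for v in extra):
                    continue
                w = 1.0
                for v in extra:
                    w /= self.factor_levels[v]
                for u in self.term_cols[other]:
                    utags = self.col_tags[u]
                    if all(utags.get(v) == base.get(v) for v in tvars):
                        l[u] += w
            rows.append(l)
        return np.vstack(rows)


# --------------------------------------------------------------------------
# Satterthwaite machinery for the random-intercept model
# --------------------------------------------------------------------------

class _BlockStats:
    """Per-participant sufficient statistics for V_i = s2 I + t2 11'."""

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.X = X[order]
        self.y = y[order]
        c = codes[order]
        self.starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(c)) + 1, [len(c)]])
        self.n_groups = len(self.starts) - 1
        self.G = []  # X_i' X_i
        self.s = []  # X_i' 1
        self.ns = []
        for g in range(self.n_groups):
            a, b = self.starts[g], self.starts[g + 1]
            Xi = self.X[a:b]
            self.G.append(Xi.T @ Xi)
            self.s.append(Xi.sum(axis=0))
            self.ns.append(b - a)

    def assemble(self, s2: float, t2: float) -> dict:
        """A, B_k, M_km and the T1 traces for theta = (s2, t2)."""
        p = self.X.shape[1]
        A = np.zeros((p, p))
        B_s = np.zeros((p, p))
        B_t = np.zeros((p, p))
        M_ss = np.zeros((p, p))
        M_st = np.zeros((p, p))
        M_tt = np.zeros((p, p))
        T1_ss = T1_st = T1_tt = 0.0
        for G, s, n in zip(self.G, self.s, self.ns):
            d = 1.0 / (s2 + n * t2)
            ss = np.outer(s, s)
            A += G / s2 + (d - 1.0 / s2) / n * ss
            B_s += G / s2**2 + (d**2 - 1.0 / s2**2) / n * ss
            B_t += d**2 * ss
            M_ss += G / s2**3 + (d**3 - 1.0 / s2**3) / n * ss
            M_st += d**3 * ss
            M_tt += n * d**3 * ss
            T1_ss += (n - 1) / s2**2 + d**2
            T1_st += n * d**2
            T1_tt += (n * d) ** 2
        return dict(A=A, B=(B_s, B_t), M=((M_ss, M_st), (M_st, M_tt)),
                    T1=np.array([[T1_ss, T1_st], [T1_st, T1_tt]]))


def _satterthwaite_cov(parts: dict) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (A_inv, grad helpers [A^-1 B_k A^-1], cov of (s2, t2))."""
    A_inv = np.linalg.inv(parts["A"])
    B = parts["B"]
    M = parts["M"]
    info = np.empty((2, 2))
    for k in range(2):
        for m in range(2):
            info[k, m] = 0.5 * (
                parts["T1"][k, m]
                - 2.0 * np.trace(A_inv @ M[k][m])
                + np.trace(A_inv @ B[k] @ A_inv @ B[m]))
    theta_cov = np.linalg.pinv(info)
    grad_mats = [A_inv @ B[k] @ A_inv for k in range(2)]
    return A_inv, grad_mats, theta_cov


def _contrast_df(l: np.ndarray, A_inv: np.ndarray,
                 grad_mats: Sequence[np.ndarray],
                 theta_cov: np.ndarray) -> Tuple[float, float]:
    """Satterthwaite df and variance for a single contrast l'beta."""
    f = float(l @ A_inv @ l)
    grad = np.array([float(l @ gm @ l) for gm in grad_mats])
    denom = float(grad @ theta_cov @ grad)
    df = 2.0 * f * f / denom if denom > 0 else np.inf
    return df, f


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # term, coef, se, df, t, p
    anova: pd.DataFrame          # term, F, df_num, df_den, p
    var_explained: float
    random_intercept_var: float
    residual_var: float
    converged: bool
    n_obs: int
    n_groups: int
    model: str = "random-intercept"


def _wald_anova(
    beta: np.ndarray,
    design: "Design",
    A_inv: np.ndarray,
    grad_mats: Optional[Sequence[np.ndarray]],
    theta_cov: Optional[np.ndarray],
    ols_df: Optional[float],
) -> pd.DataFrame:
    rows = []
    for term in design.term_cols:
        L = design.type3_contrast(term)
        C = L @ A_inv @ L.T
        r = L.shape[0]
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(C, Lb)) / r
        if ols_df is not None:
            df_den = float(ols_df)
        else:
            # lmerTest-style combination of per-eigencontrast Satterthwaite dfs
            eigval, eigvec = np.linalg.eigh(C)
            nus = []
            for j in range(r):
                lj = L.T @ eigvec[:, j]
                nu_j, _ = _contrast_df(lj, A_inv, grad_mats, theta_cov)
                nus.append(nu_j)
            E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
            df_den = 2.0 * E / (E - r) if E > r else float(2 * r)
        p = float(sps.f.sf(F, r, df_den))
        rows.append({"term": term, "F": F, "df_num": r,
                     "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


def _fit_random_intercept(
    y: np.ndarray, codes: np.ndarray, design: "Design",
) -> MixedModelResult:
    X, names = design.X, design.names
    import statsmodels.api as sm

    res = None
    last_err: Optional[Exception] = None
    for method in (None, "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = sm.MixedLM(y, X, groups=codes)
                res = (mod.fit(reml=True) if method is None
                       else mod.fit(reml=True, method=method))
            if res.converged:
                break
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            res = None
    if res is None:
        raise RuntimeError(f"mixed-model REML fit failed: {last_err}")
    if not res.converged:
        raise RuntimeError(
            "mixed-model REML fit did not converge "
            f"(groups={len(np.unique(codes))}, n={len(y)})")
    s2 = float(res.scale)
    t2 = float(np.asarray(res.cov_re).ravel()[0])

    blocks = _BlockStats(X, y, codes)
    parts = blocks.assemble(s2, max(t2, 0.0))
    A_inv, grad_mats, theta_cov = _satterthwaite_cov(parts)
    beta = np.asarray(res.fe_params, dtype=float)

    fe_rows = []
    for i, name in enumerate(names):
        l = np.zeros(beta.size)
        l[i] = 1.0
        df_i, var_i = _contrast_df(l, A_inv, grad_mats, theta_cov)
        se = np.sqrt(var_i)
        t = beta[i] / se
        fe_rows.append({"term": name, "coef": beta[i], "se": se,
                        "df": df_i, "t": t,
                        "p": float(2 * sps.t.sf(abs(t), df_i))})
    fixed = pd.DataFrame(fe_rows)
    anova = _wald_anova(beta, design, A_inv, grad_mats, theta_cov, None)

    fitted = X @ beta
    var_explained = float(np.corrcoef(fitted, y)[0, 1] ** 2) \
        if np.std(fitted) > 0 else 0.0
    return MixedModelResult(
        fixed_effects=fixed, anova=anova, var_explained=var_explained,
        random_intercept_var=t2, residual_var=s2, converged=bool(res.converged),
        n_obs=len(y), n_groups=len(np.unique(codes)))


def _fit_ols(y: np.ndarray, design: "Design") -> MixedModelResult:
    X, names = design.X, design.names
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    A_inv = s2 * np.linalg.inv(X.T @ X)
    fe_rows = []
    for i, name in enumerate(names):
        se = np.sqrt(A_inv[i, i])
        t = beta[i] / se
        fe_rows.append({"term": name, "coef": beta[i], "se": se,
                        "df": float(df), "t": t,
                        "p": float(2 * sps.t.sf(abs(t), df))})
    fixed = pd.DataFrame(fe_rows)
    anova = _wald_anova(beta, design, A_inv, None, None, float(df))
    fitted = X @ beta
    var_explained = float(np.corrcoef(fitted, y)[0, 1] ** 2) \
        if np.std(fitted) > 0 else 0.0
    return MixedModelResult(
        fixed_effects=fixed, anova=anova, var_explained=var_explained,
        random_intercept_var=0.0, residual_var=s2, converged=True,
        n_obs=n, n_groups=n, model="ols")


def _merged_frame(
    summary: pd.DataFrame,
    volume_w: WScoreTable,
    meta: pd.DataFrame,
    moderator: str,
) -> pd.DataFrame:
    vol = volume_w.table.rename(columns={"target_id": "region", "w": "gm_w"})
    df = summary.merge(vol, on=["participant_id", "region"], how="inner")
    cols = ["participant_id", "group", "phenotype", "apoe_e4_count"]
    df = df.merge(meta[cols], on="participant_id", how="left")
    if moderator == "apoe_e4_count":
        df = df[df["apoe_e4_count"].notna()].copy()
        df["apoe_e4_count"] = df["apoe_e4_count"].astype(int).astype(str)
    df = df[np.isfinite(df["gm_w"]) & np.isfinite(df["mean_wm_w"])]
    return df.reset_index(drop=True)


def fit_gmwm(
    summary: pd.DataFrame,
    volume_w: WScoreTable,
    meta: pd.DataFrame,
    moderator: str = "group",
    random_intercept: bool = True,
) -> MixedModelResult:
    """Mean WM w-score ~ moderator * GM w-score (+ random intercept).

    ``moderator`` is ``group``, ``phenotype`` or ``apoe_e4_count`` (copy
    number treated as a 3-level factor; rows without genotype dropped).
    With ``random_intercept=False`` the random-intercept variance is pinned
    at zero, which reduces the fit to pooled OLS with residual df.
    """
    if moderator not in ("group", "phenotype", "apoe_e4_count"):
        raise ValueError(f"unsupported moderator {moderator!r}")
    df = _merged_frame(summary, volume_w, meta, moderator)
    levels = level_order(df[moderator].unique())
    if len(levels) < 2:
        raise ValueError("moderator needs at least 2 levels with data")
    design = _build_design(
        df, factors={moderator: levels}, continuous=["gm_w"],
        interactions=[(moderator, "gm_w")])
    y = df["mean_wm_w"].to_numpy(float)
    codes = pd.factorize(df["participant_id"])[0]
    if random_intercept:
        return _fit_random_intercept(y, codes, design)
    return _fit_ols(y, design)


def fit_gmwm_apoe(
    summary: pd.DataFrame,
    volume_w: WScoreTable,
    meta: pd.DataFrame,
    model: str = "additive",
) -> MixedModelResult:
    """APOE e4 moderation adjusted for diagnostic group.

    ``model='additive'`` fits group + e4 copy number + GM w-score;
    ``model='full'`` adds every two- and three-way interaction.
    """
    df = _merged_frame(summary, volume_w, meta, "apoe_e4_count")
    g_levels = level_order(df["group"].unique())
    a_levels = level_order(df["apoe_e4_count"].unique())
    factors = {"group": g_levels, "apoe_e4_count": a_levels}
    if model == "additive":
        interactions: List[Tuple[str, ...]] = []
    elif model == "full":
        interactions = [("group", "apoe_e4_count"), ("group", "gm_w"),
                        ("apoe_e4_count", "gm_w"),
                        ("group", "apoe_e4_count", "gm_w")]
    else:
        raise ValueError("model must be 'additive' or 'full'")
    design = _build_design(
        df, factors=factors, continuous=["gm_w"], interactions=interactions)
    y = df["mean_wm_w"].to_numpy(float)
    codes = pd.factorize(df["participant_id"])[0]
    return _fit_random_intercept(y, codes, design)
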