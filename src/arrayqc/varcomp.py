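"""Variance decomposition of per-array quality summaries.

Model: response_i = mu + S_j(i) + L_k(i) + eps_i, a crossed two-factor
random-effects ANOVA with S the sample-type effect, L the lab effect and no
interaction.  Components are estimated by Henderson-type method of moments:
the quadratic forms T_A - T_mu, T_B - T_mu and the residual form are
equated to their expectations, which are linear in (sigma2_eps, sigma2_S,
sigma2_L) with coefficients computed from the (possibly unbalanced) cell
counts.  Negative moment solutions are truncated at zero and recorded.

Also provides the per-tissue one-way fixed-effects ANOVA of (log) quality
responses on lab, with sum-to-zero lab effects and per-lab t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError


@dataclass
class VarianceComponents:
    mu: float
    var_sample_type: float | None   # None when inestimable (single level)
    var_lab: float | None
    var_resid: float
    n_sample_types: int
    n_labs: int
    estimator_name: str = "henderson_moments"
    truncated: list[str] = field(default_factory=list)

    @property
    def lab_to_sample_type_ratio(self) -> float | None:
        if not self.var_sample_type or self.var_lab is None:
            return None
        return self.var_lab / self.var_sample_type


def fit_varcomp(table: pd.DataFrame, response: str = "response",
                sample_type: str = "sample_type", lab: str = "lab") -> VarianceComponents:
    """Method-of-moments fit of the crossed two-factor random model.

    Needs >= 2 levels per factor for that factor's component to be
    estimable; with a single level the component is reported as None and
    its variability is absorbed by the residual.
    """
    y = table[response].to_numpy(dtype=float)
    st = table[sample_type].astype(str).to_numpy()
    lb = table[lab].astype(str).to_numpy()
    N = len(y)
    types = np.unique(st)
    labs = np.unique(lb)
    J, K = len(types), len(labs)
    if N < 3:
        raise ValidationError("need >= 3 observations")

    if J < 2 or K < 2:
        # degenerate: only the other factor + residual identifiable; keep it
        # simple and honest — report the inestimable component as None.
        grand = float(y.mean())
        if J < 2 and K < 2:
            return VarianceComponents(grand, None, None,
                                      float(y.var(ddof=1)), J, K)
        factor, levels = (lb, labs) if K >= 2 else (st, types)
        sums = {lv: y[factor == lv].sum() for lv in levels}
        ns = {lv: int((factor == lv).sum()) for lv in levels}
        T_f = sum(sums[lv] ** 2 / ns[lv] for lv in levels)
        T_mu = y.sum() ** 2 / N
        T_0 = float((y ** 2).sum())
        L = len(levels)
        c = N - sum(n ** 2 for n in ns.values()) / N
        mse = (T_0 - T_f) / (N - L)
        msf = (T_f - T_mu) / (L - 1)
        var_f = max((msf - mse) * (L - 1) / c, 0.0)
        truncated = ["factor"] if (msf - mse) < 0 else []
        if K >= 2:
            return VarianceComponents(grand, None, var_f, mse, J, K,
                                      truncated=truncated)
        return VarianceComponents(grand, var_f, None, mse, J, K,
                                  truncated=truncated)

    # cross-tabulated counts and factor sums
    n_jk = pd.crosstab(pd.Series(st), pd.Series(lb)).to_numpy(dtype=float)
    n_j = n_jk.sum(axis=1)
    n_k = n_jk.sum(axis=0)
    sum_j = np.array([y[st == t].sum() for t in types])
    sum_k = np.array([y[lb == l].sum() for l in labs])

    T_A = float((sum_j ** 2 / n_j).sum())
    T_B = float((sum_k ** 2 / n_k).sum())
    T_mu = float(y.sum() ** 2 / N)
    T_0 = float((y ** 2).sum())

    qA = T_A - T_mu
    qB = T_B - T_mu
    qE = T_0 - T_A - T_B + T_mu

    # expectation coefficients of each quadratic form in
    # (sigma2_eps, sigma2_S, sigma2_L); mu terms cancel by construction
    sj2N = float((n_j ** 2).sum() / N)
    sk2N = float((n_k ** 2).sum() / N)
    cross_A = float((n_jk ** 2 / n_j[:, None]).sum())   # tr within type means
    cross_B = float((n_jk ** 2 / n_k[None, :]).sum())
    A_mat = np.array([
        [J - 1, N - sj2N, cross_A - sk2N],
        [K - 1, cross_B - sj2N, N - sk2N],
        [N - J - K + 1, sj2N - cross_B, sk2N - cross_A],
    ])
    sol = np.linalg.solve(A_mat, np.array([qA, qB, qE]))
    var_eps, var_S, var_L = sol
    truncated = []
    if var_S < 0:
        truncated.append("sample_type")
        var_S = 0.0
    if var_L < 0:
        truncated.append("lab")
        var_L = 0.0
    if var_eps < 0:
        truncated.append("residual")
        var_eps = 0.0
    return VarianceComponents(
        mu=float(y.mean()),
        var_sample_type=float(var_S),
        var_lab=float(var_L),
        var_resid=float(var_eps),
        n_sample_types=J,
        n_labs=K,
        truncated=truncated,
    )


@dataclass
class OneWayAnova:
    """One-way fixed-effects ANOVA of quality responses on lab."""

    effects: dict[str, float]       # lab mean minus unweighted grand mean
    n_per_lab: dict[str, int]
    f_statistic: float
    p_value: float
    lab_p_values: dict[str, float]
    significant: dict[str, bool]    # per-lab p < 0.05 ("starred")


def oneway_lab_anova(table: pd.DataFrame, response: str = "response",
                     lab: str = "lab", log_transform: bool = False) -> OneWayAnova:
    """Per-tissue one-way ANOVA of (optionally log-transformed) responses.

    Lab effects use sum-to-zero coding (deviation of the lab mean from the
    unweighted mean of lab means, so signed quality differences between
    labs are directly readable).  The F test is the classical equal-means
    test; per-lab t-tests compare each lab mean to the grand mean using the
    pooled residual variance.  Zero residual variance is degenerate: p = 0
    if any effects differ, else 1.
    """
    y = table[response].to_numpy(dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValidationError("log transform requires positive responses")
        y = np.log(y)
    lb = table[lab].astype(str).to_numpy()
    labs = sorted(np.unique(lb))
    if len(labs) < 2:
        raise ValidationError("need >= 2 labs")
    groups = {l: y[lb == l] for l in labs}
    if any(len(g) < 1 for g in groups.values()):
        raise ValidationError("every lab needs >= 1 observation")
    N, J = len(y), len(labs)
    if N - J < 1:
        raise ValidationError("need >= 2 observations total per lab on average")

    means = {l: float(g.mean()) for l, g in groups.items()}
    grand = float(np.mean(list(means.values())))
    effects = {l: means[l] - grand for l in labs}
    n_per = {l: int(len(groups[l])) for l in labs}

    sse = sum(float(((g - means[l]) ** 2).sum()) for l, g in groups.items())
    ssb = sum(n_per[l] * (means[l] - y.mean()) ** 2 for l in labs)
    df_b, df_e = J - 1, N - J
    if sse == 0:
        distinct = len({round(v, 12) for v in means.values()}) > 1
        f_stat = np.inf if distinct else 0.0
        p_val = 0.0 if distinct else 1.0
        lab_p = {l: (0.0 if effects[l] != 0 else 1.0) for l in labs}
    else:
        mse = sse / df_e
        f_stat = (ssb / df_b) / mse
        p_val = float(stats.f.sf(f_stat, df_b, df_e))
        lab_p = {}
        for l in labs:
            se = np.sqrt(mse / n_per[l])
            t = effects[l] / se
            lab_p[l] = float(2 * stats.t.sf(abs(t), df_e))
    return OneWayAnova(
        effects=effects,
        n_per_lab=n_per,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        lab_p_values=lab_p,
        significant={l: lab_p[l] < 0.05 for l in labs},
    )
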