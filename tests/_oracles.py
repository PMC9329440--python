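"""Independent brute-force oracles used only by the tests.

Each function re-derives a statistic by the most transparent route available
(double loops, exhaustive enumeration, generic numerical optimization) and is
kept deliberately separate from the library implementations it checks.
"""

import numpy as np
from scipy import optimize


def naive_prs(score, panel):
    """Double-loop weighted dosage sum, honouring flip flags."""
    out = np.zeros(panel.n_individuals)
    for v in score.variants:
        i = panel.index_of(v.variant_id, v.chromosome, v.position)
        for j in range(panel.n_individuals):
            d = panel.dosages[i, j]
            if v.flip_dosage:
                d = 2.0 - d
            out[j] += v.weight * d
    return out


def brute_auc(risk, outcome):
    """All-pairs concordance probability; ties count one half."""
    risk = np.asarray(risk, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    cases = risk[outcome == 1]
    controls = risk[outcome == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


def enum_nri(p_old, p_new, outcome):
    """Direct enumeration of the continuous-NRI decomposition."""
    up_case = down_case = up_ctrl = down_ctrl = 0
    n_case = n_ctrl = 0
    for po, pn, y in zip(p_old, p_new, outcome):
        if y == 1:
            n_case += 1
            up_case += pn > po
            down_case += pn < po
        else:
            n_ctrl += 1
            up_ctrl += pn > po
            down_ctrl += pn < po
    return (up_case - down_case) / n_case + (down_ctrl - up_ctrl) / n_ctrl


def optimize_logistic(outcome, design):
    """Generic minimizer of the negative log-likelihood (no IRLS)."""
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)

    def nll(beta):
        eta = X @ beta
        # log(1+exp(eta)) - y*eta, stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS", options={"gtol": 1e-10})
    return res.x
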