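"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's m-array code paths: probabilities are
computed per individual by exhaustively summing over the unobserved death
time, so they can certify the marginalized multinomial likelihood.
"""

import numpy as np

JUVENILE = 0


def history_logprob(y, tau, age, phi_ad, phi_juv, p_ad, p_sy=None):
    """Log-probability of one encounter history after release.

    Occasions are 0-based.  ``phi_*[k]`` is survival over interval k -> k+1;
    ``p_ad[t]`` is the detection probability at occasion t; ``p_sy``
    (defaulting to ``p_ad``) applies at the occasion immediately after a
    juvenile release.  The latent alive/dead state is marginalized by
    summing over d = the last occasion alive.
    """
    if p_sy is None:
        p_sy = p_ad
    T = len(y)
    detections = [t for t in range(tau + 1, T) if y[t] == 1]
    last_det = detections[-1] if detections else tau

    def phi_at(k):
        if age == JUVENILE and k == tau:
            return phi_juv[k]
        return phi_ad[k]

    def p_at(t):
        if age == JUVENILE and t == tau + 1:
            return p_sy[t]
        return p_ad[t]

    total = 0.0
    for d in range(last_det, T):  # last occasion alive
        pr = 1.0
        for k in range(tau, d):
            pr *= phi_at(k)
        if d < T - 1:
            pr *= 1.0 - phi_at(d)
        for t in range(tau + 1, d + 1):
            pr *= p_at(t) if y[t] == 1 else 1.0 - p_at(t)
        total += pr
    return np.log(total)


def dataset_loglik(histories, phi_ad, phi_juv, p_ad, p_sy=None):
    """Sum of per-individual marginal log-probabilities."""
    return float(
        sum(
            history_logprob(
                histories.y[i],
                int(histories.tau[i]),
                int(histories.age_at_release[i]),
                phi_ad,
                phi_juv,
                p_ad,
                p_sy,
            )
            for i in range(histories.n_individuals)
        )
    )
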