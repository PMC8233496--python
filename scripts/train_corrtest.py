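"""Fit the frozen logistic coefficients of the rate-autocorrelation test.

Simulates Yule trees dressed with either independent-lognormal branch rates
(class 0) or autocorrelated geometric-Brownian rates (class 1) across a
range of tip counts and rate variances, computes the correlation features of
the estimated lineage rates, and fits a logistic regression.  The resulting
intercept/coefficients are pasted into ``chronotree/corrtest.py`` as frozen
constants; this script records the procedure and seed.

Run from the repository root:  python scripts/train_corrtest.py
"""

import numpy as np

from chronotree.corrtest import FEATURE_NAMES, rate_features
from chronotree.simulate import SimulationConfig, apply_rate_model, simulate_timetree

SEED = 20260924
N_PER_CLASS = 600
TIP_COUNTS = (50, 100, 200, 300)
NULL_SDLOGS = (0.2, 0.3, 0.5)
ALT_STEP_SDLOGS = (0.1, 0.2, 0.3)


def simulate_features(rng, rate_model, **kw):
    cfg = SimulationConfig(
        n_tips=int(rng.choice(TIP_COUNTS)),
        seed=int(rng.integers(2**31 - 1)),
        rate_model=rate_model,
        mu=1.0,
        **kw,
    )
    srng = cfg.rng()
    phylo = apply_rate_model(simulate_timetree(cfg, srng), cfg, srng)
    f = rate_features(phylo)
    return [f[k] for k in FEATURE_NAMES]


def main():
    rng = np.random.default_rng(SEED)
    X, y = [], []
    for _ in range(N_PER_CLASS):
        X.append(
            simulate_features(
                rng, "iid_lognormal", sdlog=float(rng.choice(NULL_SDLOGS))
            )
        )
        y.append(0)
        X.append(
            simulate_features(
                rng, "autocorrelated", step_sdlog=float(rng.choice(ALT_STEP_SDLOGS))
            )
        )
        y.append(1)
    X, y = np.array(X), np.array(y)

    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, max_iter=5000).fit(X, y)
    acc = clf.score(X, y)
    print(f"training accuracy: {acc:.3f}  (n = {len(y)})")
    print(f"_LOGISTIC_INTERCEPT = {clf.intercept_[0]:.6f}")
    coefs = ", ".join(f"{c:.6f}" for c in clf.coef_[0])
    print(f"_LOGISTIC_COEF = np.array([{coefs}])")


if __name__ == "__main__":
    main()
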