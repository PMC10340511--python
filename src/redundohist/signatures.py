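"""Maximum-likelihood refitting of SBS96 profiles against a signature catalog.

Given channel counts n_c and catalog columns S_k (probability over the 96
channels), the exposures w maximize the multinomial log-likelihood

    L(w) = sum_c n_c * log( sum_k w_k S_ck ),   w >= 0, sum_k w_k = 1,

reported as percentages of mutations attributed to each process. The
optimizer is expectation-maximization with closed-form updates

    w_k  <-  (1/N) * sum_c n_c * w_k S_ck / sum_j w_j S_cj ,

which is monotone in L; L is concave in w on the simplex, so the uniform
initialization converges to the global optimum. A flat 1/96 column can be
appended to absorb context-free mutational processes.

Robustness is assessed by a multinomial bootstrap: the profile is resampled
with replacement at its own size, each resample is refit, and the 2.5/97.5
percentiles form the 95% CI. A signature is called active when its
point-estimate exposure exceeds 5%. Signatures sharing an annotated etiology
(UV light, mismatch-repair deficiency, POLE/POLD1 deficiency, tobacco,
APOBEC) can be merged by summing exposures.
"""

from __future__ import annotations

import numpy as np

from .model import DecompositionResult, MutationalProfile, SignatureCatalog

FLAT_NAME = "Flat"

#: COSMIC v3 signatures grouped by shared annotated etiology.
ETIOLOGY_GROUPS: dict[str, list[str]] = {
    "UV": ["SBS7a", "SBS7b", "SBS7c", "SBS7d"],
    "MMR": ["SBS6", "SBS15", "SBS21", "SBS26", "SBS44"],
    "POLE": ["SBS10a", "SBS10b"],
    "POLD1": ["SBS10c", "SBS10d"],
    "Tobacco": ["SBS4", "SBS92"],
    "APOBEC": ["SBS2", "SBS13"],
}

_FLOOR = 1e-300  # guards log/div of channels where the mixture mass is zero


def _em_fit(
    counts: np.ndarray,
    S: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """EM on the multinomial mixture; returns (weights, log-likelihood)."""
    n_sig = S.shape[1]
    w = np.full(n_sig, 1.0 / n_sig)
    total = counts.sum()
    obs = counts > 0
    S_obs = S[obs]
    n_obs = counts[obs]
    ll_prev = -np.inf
    for _ in range(max_iter):
        mix = S_obs @ w
        ll = float(n_obs @ np.log(np.maximum(mix, _FLOOR)))
        if ll - ll_prev <= tol * max(abs(ll_prev), 1.0) and ll_prev != -np.inf:
            break
        ll_prev = ll
        resp = S_obs * w / np.maximum(mix, _FLOOR)[:, None]
        w = (n_obs @ resp) / total
        w = np.maximum(w, 0)
        w /= w.sum()
    mix = S_obs @ w
    ll = float(n_obs @ np.log(np.maximum(mix, _FLOOR)))
    return w, ll


def _catalog_matrix(
    catalog: SignatureCatalog, include_flat: bool
) -> tuple[np.ndarray, list[str]]:
    S = catalog.matrix
    names = list(catalog.signature_names)
    if include_flat:
        S = np.column_stack([S, np.full(96, 1.0 / 96)])
        names = names + [FLAT_NAME]
    return S, names


def decompose(
    profile: MutationalProfile,
    catalog: SignatureCatalog,
    include_flat: bool = False,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> DecompositionResult:
    """Point-estimate exposures (percent) maximizing the multinomial likelihood."""
    if profile.total == 0:
        raise ValueError(f"profile {profile.label!r} has no mutations")
    S, names = _catalog_matrix(catalog, include_flat)
    counts = profile.counts.astype(float)
    w, ll = _em_fit(counts, S, tol=tol, max_iter=max_iter)
    exposures = {name: 100.0 * float(wk) for name, wk in zip(names, w)}
    # exact renormalization of float drift so the contract sum == 100 holds
    total = sum(exposures.values())
    exposures = {k: v * 100.0 / total for k, v in exposures.items()}
    active = frozenset(k for k, v in exposures.items() if v > 5.0)
    return DecompositionResult(
        exposures=exposures, log_likelihood=ll, n_mutations=profile.total,
        active=active,
    )


def bootstrap_decompose(
    profile: MutationalProfile,
    catalog: SignatureCatalog,
    n_boot: int = 100,
    seed: int | None = None,
    include_flat: bool = False,
    active_threshold: float = 5.0,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> DecompositionResult:
    """Refit with percentile bootstrap CIs.

    Each of ``n_boot`` resamples draws ``profile.total`` mutations
    multinomially from the normalized profile and is decomposed; the 2.5th
    and 97.5th percentiles across resamples form the 95% CI and the mean is
    reported alongside. The active set thresholds the point estimate.
    """
    point = decompose(profile, catalog, include_flat=include_flat,
                      tol=tol, max_iter=max_iter)
    S, names = _catalog_matrix(catalog, include_flat)
    rng = np.random.default_rng(seed)
    probs = profile.normalized
    draws = rng.multinomial(profile.total, probs, size=n_boot)
    boot = np.empty((n_boot, len(names)))
    for b in range(n_boot):
        w, _ = _em_fit(draws[b].astype(float), S, tol=tol, max_iter=max_iter)
        boot[b] = 100.0 * w
    mean = boot.mean(axis=0)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    active = frozenset(
        k for k, v in point.exposures.items() if v > active_threshold
    )
    return DecompositionResult(
        exposures=point.exposures,
        log_likelihood=point.log_likelihood,
        n_mutations=profile.total,
        bootstrap_mean=dict(zip(names, mean)),
        ci_low=dict(zip(names, np.minimum(lo, mean))),
        ci_high=dict(zip(names, np.maximum(hi, mean))),
        active=active,
    )


def merge_etiologies(
    exposures: dict[str, float],
    groups: dict[str, list[str]] | None = None,
) -> dict[str, float]:
    """Sum exposures of signatures sharing an etiology; others pass through.

    A group member absent from the exposures contributes nothing (partial
    sum). The grand total is preserved.
    """
    if groups is None:
        groups = ETIOLOGY_GROUPS
    member_of: dict[str, str] = {}
    for gname, members in groups.items():
        for m in members:
            member_of[m] = gname
    merged: dict[str, float] = {}
    for sig, value in exposures.items():
        key = member_of.get(sig, sig)
        merged[key] = merged.get(key, 0.0) + value
    return merged


def grid_search_decompose(
    profile: MutationalProfile,
    catalog: SignatureCatalog,
    resolution: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Brute-force simplex grid maximizer of the multinomial likelihood.

    Exhaustive over weight vectors with entries on a ``resolution`` lattice;
    intended as an independent optimality check for K <= 3 (cost grows as
    (1/resolution)^(K-1)).
    """
    S = catalog.matrix
    k = S.shape[1]
    if k > 3:
        raise ValueError("grid search supported for K <= 3 only")
    counts = profile.counts.astype(float)
    steps = int(round(1 / resolution))

    def ll_of(w: np.ndarray) -> float:
        mix = S @ w
        return float(counts @ np.log(np.maximum(mix, _FLOOR)))

    best_w, best_ll = None, -np.inf
    if k == 1:
        return np.array([1.0]), ll_of(np.array([1.0]))
    if k == 2:
        for i in range(steps + 1):
            w = np.array([i / steps, 1 - i / steps])
            ll = ll_of(w)
            if ll > best_ll:
                best_w, best_ll = w, ll
    else:
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                w = np.array([i / steps, j / steps, 1 - (i + j) / steps])
                ll = ll_of(w)
                if ll > best_ll:
                    best_w, best_ll = w, ll
    return best_w, best_ll
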