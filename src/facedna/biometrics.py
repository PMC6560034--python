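"""Biometric evaluation: identification (CMC) and verification (ROC).

Identification is one-to-many: a probe DNA profile is matched against a
gallery of faces sorted by overall matching score; the rank is the
position of the true face (mid-rank under ties) and the CMC curve is the
cumulative fraction of probes identified by each rank.  The rank-x% rate
is the CMC value at ceil(x% of the gallery size).

Verification is one-to-one: genuine and imposter score distributions give
a ROC of true-positive versus false-positive fractions, summarized by the
area under the curve (tie-aware, equal to P(genuine > imposter) + half the
tie probability) and the equal error rate, interpolated where the
false-accept and false-reject fractions cross.  Random scores give
EER = 0.5, AUC = 0.5 and a rank-x% rate of x%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from facedna.fusion import build_genuine_imposter, fuse, train_fuser

__all__ = [
    "CMCCurve",
    "ROCCurve",
    "identification_cmc",
    "verification_roc",
    "evaluate_feature_subsets",
    "plot_curves",
]


@dataclass
class CMCCurve:
    """Cumulative match characteristic over gallery ranks."""

    rates: np.ndarray  # (G,), rates[r-1] = fraction of probes with rank <= r
    gallery_size: int
    ranks: np.ndarray = field(repr=False, default=None)

    def rate_at_rank(self, rank: int) -> float:
        rank = int(np.clip(rank, 1, self.gallery_size))
        return float(self.rates[rank - 1])

    def rank_percent_rate(self, percent: float) -> float:
        """Fraction of probes whose match is within the top ``percent``%."""
        return self.rate_at_rank(ceil(percent / 100.0 * self.gallery_size))


@dataclass
class ROCCurve:
    """Verification trade-off with EER and AUC summaries."""

    fpf: np.ndarray
    tpf: np.ndarray
    thresholds: np.ndarray
    eer: float
    auc: float
    degenerate: bool = False


def identification_cmc(
    score_matrix: np.ndarray, true_index: np.ndarray
) -> CMCCurve:
    """CMC from a probes x gallery score matrix.

    ``true_index[i]`` is the gallery column holding probe i's true face
    (negative to mark a probe with no true match, which is excluded with a
    warning).  Ties in the sorted gallery are resolved mid-rank.
    """
    S = np.asarray(score_matrix, float)
    t = np.asarray(true_index, int)
    if S.ndim != 2 or len(t) != S.shape[0]:
        raise ValueError("need (probes, gallery) scores and one true index per probe")
    ok = t >= 0
    if not ok.all():
        warnings.warn(f"{np.sum(~ok)} probes without a true match excluded")
        S, t = S[ok], t[ok]
    G = S.shape[1]
    s_true = S[np.arange(len(t)), t]
    greater = np.sum(S > s_true[:, None], axis=1)
    ties = np.sum(S == s_true[:, None], axis=1) - 1  # other gallery faces tied
    ranks = greater + 1 + ties / 2.0
    rates = np.array([np.mean(ranks <= r) for r in range(1, G + 1)])
    return CMCCurve(rates=rates, gallery_size=G, ranks=ranks)


def verification_roc(
    genuine_scores: np.ndarray, imposter_scores: np.ndarray
) -> ROCCurve:
    """ROC, tie-aware AUC and interpolated EER from two score samples."""
    g = np.asarray(genuine_scores, float).ravel()
    i = np.asarray(imposter_scores, float).ravel()
    if g.size == 0 or i.size == 0:
        raise ValueError("both score lists must be non-empty")
    scores = np.concatenate([g, i])
    labels = np.concatenate([np.ones_like(g), np.zeros_like(i)])
    if np.ptp(scores) == 0:
        return ROCCurve(
            fpf=np.array([0.0, 1.0]), tpf=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, scores[0]]),
            eer=0.5, auc=0.5, degenerate=True,
        )
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    # EER: crossing of FPF and 1 - TPF along the curve, linearly interpolated
    fnr = 1.0 - tpr
    diff = fpr - fnr
    k = int(np.argmax(diff >= 0))
    if diff[k] == 0 or k == 0:
        eer = float(fpr[k]) if diff[k] == 0 else float((fpr[0] + fnr[0]) / 2)
    else:
        x0, x1 = diff[k - 1], diff[k]
        w = -x0 / (x1 - x0)
        eer = float((1 - w) * (fpr[k - 1] + fnr[k - 1]) / 2 + w * (fpr[k] + fnr[k]) / 2)
    return ROCCurve(fpf=fpr, tpf=tpr, thresholds=thr, eer=eer, auc=auc)


def evaluate_feature_subsets(
    validation_scores: np.ndarray,
    test_scores: np.ndarray,
    feature_names: list[str],
    subsets: dict[str, list[str]],
    prior_mode: str = "empirical",
) -> pd.DataFrame:
    """Fuse and evaluate ordered feature subsets on one fold.

    ``validation_scores`` and ``test_scores`` are (n x n x d) all-vs-all
    match-score tensors (faces x probes x features).  For each subset a
    fuser is trained on the validation tensor restricted to the subset's
    features and applied to the test tensor; identification uses each
    probe's column against the full gallery, verification uses the
    diagonal as genuine and off-diagonal as imposter scores.  A subset
    with no deployed features is reported as a random-baseline row
    (EER/AUC 0.5, rank-x% = x%).
    """
    name_to_col = {n: j for j, n in enumerate(feature_names)}
    rows = []
    n_test = test_scores.shape[0]
    for subset_name, members in subsets.items():
        cols = [name_to_col[m] for m in members if m in name_to_col]
        if not cols:
            rows.append(
                {
                    "subset": subset_name, "n_features": 0,
                    "eer": 0.5, "auc": 0.5,
                    "r1": 1.0, "r10": 10.0, "r20": 20.0,
                    "baseline": True,
                }
            )
            continue
        gi = build_genuine_imposter(
            validation_scores[:, :, cols], [feature_names[c] for c in cols]
        )
        fuser = train_fuser(gi, prior_mode=prior_mode)
        flat = test_scores[:, :, cols].reshape(-1, len(cols))
        fused = fuse(fuser, flat).reshape(n_test, n_test)
        # probes index columns: probe j's scores against the gallery are fused[:, j]
        cmc = identification_cmc(fused.T, np.arange(n_test))
        genuine = np.diag(fused)
        mask = ~np.eye(n_test, dtype=bool)
        roc = verification_roc(genuine, fused[mask])
        rows.append(
            {
                "subset": subset_name, "n_features": len(cols),
                "eer": roc.eer, "auc": roc.auc,
                "r1": 100.0 * cmc.rank_percent_rate(1),
                "r10": 100.0 * cmc.rank_percent_rate(10),
                "r20": 100.0 * cmc.rank_percent_rate(20),
                "baseline": False,
            }
        )
    return pd.DataFrame(rows)


def plot_curves(roc: ROCCurve, cmc: CMCCurve, path) -> None:
    """Write a two-panel ROC + CMC figure (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(roc.fpf, roc.tpf, label=f"AUC={roc.auc:.3f}, EER={roc.eer:.3f}")
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax1.set_xlabel("false positive fraction")
    ax1.set_ylabel("true positive fraction")
    ax1.legend(frameon=False)
    ranks = np.arange(1, cmc.gallery_size + 1)
    ax2.plot(100 * ranks / cmc.gallery_size, cmc.rates)
    ax2.set_xlabel("rank (% of gallery)")
    ax2.set_ylabel("cumulative identification rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
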