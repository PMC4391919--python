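"""Point-wise (PW) and simultaneous (HPW) detection of credible effects.

PW inference flags an effect whose marginal posterior sign probability
q = max(P(>0), P(<0)) strictly exceeds a level alpha (default 0.975, i.e.
the 95% equal-tail credible interval excludes zero).

HPW ("highest point-wise probabilities") inference walks the candidate
effects in order of descending q and keeps adding them while the JOINT
posterior probability that every selected effect has its assigned sign
stays above a level alpha (default 0.95). Exclusion rules keep single
effects and combined effects involving the same locus from being selected
together.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combined import EffectSet

__all__ = [
    "InferenceConfig",
    "DetectionResult",
    "pw_detect",
    "joint_sign_probability",
    "hpw_select",
    "credibility_types",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Credibility levels for PW (marginal) and HPW (joint) detection."""

    alpha_pw: float = 0.975
    alpha_hpw: float = 0.95

    def __post_init__(self) -> None:
        for a in (self.alpha_pw, self.alpha_hpw):
            if not (0.5 < a < 1.0):
                raise ValueError(f"credibility level must lie in (0.5, 1), got {a}")


@dataclass
class DetectionResult:
    """Per-effect detection outcome plus the effect-set structure.

    ``sign`` is the majority posterior sign (+1/-1; a tie counts as +1),
    ``q`` the marginal sign probability and ``credible`` the detection flag
    (PW: q > alpha; HPW: selected by the greedy procedure).
    """

    labels: list[str]
    q: np.ndarray
    sign: np.ndarray
    credible: np.ndarray
    n_single: int
    pair_j: np.ndarray
    pair_k: np.ndarray
    pair_is_sum: np.ndarray
    alpha: float
    method: str
    joint_probability: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.labels,
                "q": self.q,
                "sign": np.where(self.sign > 0, "+", "-"),
                "credible": self.credible,
            }
        )


def sign_stats(effects: EffectSet) -> tuple[np.ndarray, np.ndarray]:
    """Marginal sign probability q and majority sign for every effect column.

    Draws exactly equal to zero count toward neither sign.
    """
    d = effects.draws
    if d.shape[0] < 1:
        raise ValueError("effect set holds no draws")
    p_pos = (d > 0).mean(axis=0)
    p_neg = (d < 0).mean(axis=0)
    q = np.maximum(p_pos, p_neg)
    sign = np.where(p_pos >= p_neg, 1, -1)
    return q, sign


def pw_detect(effects: EffectSet, alpha: float = 0.975) -> DetectionResult:
    """Flag effects whose marginal sign probability strictly exceeds alpha."""
    q, sign = sign_stats(effects)
    return DetectionResult(
        labels=list(effects.labels),
        q=q,
        sign=sign,
        credible=q > alpha,
        n_single=effects.n_single,
        pair_j=effects.pair_j.copy(),
        pair_k=effects.pair_k.copy(),
        pair_is_sum=effects.pair_is_sum.copy(),
        alpha=alpha,
        method="pw",
    )


def joint_sign_probability(
    effects: EffectSet, selection: list[tuple[int, int]]
) -> float:
    """Fraction of draws in which EVERY selected effect has its assigned sign.

    ``selection`` is a list of ``(column index, sign)`` pairs with sign +1
    or -1.
    """
    if not selection:
        raise ValueError("selection is empty")
    cols = [c for c, _ in selection]
    if len(set(cols)) != len(cols):
        raise ValueError("selection contains duplicate effects")
    d = effects.draws
    ok = np.ones(d.shape[0], dtype=bool)
    for c, s in selection:
        if not (0 <= c < d.shape[1]):
            raise IndexError(f"unknown effect column {c}")
        ok &= d[:, c] > 0 if s > 0 else d[:, c] < 0
    return float(ok.mean())


def _hpw_order(q: np.ndarray, n_single: int) -> list[int]:
    # Descending q; ties broken with combined effects before single effects,
    # then by ascending column index. The ordering is a fixed convention
    # chosen for determinism.
    return sorted(
        range(q.size), key=lambda c: (-q[c], 0 if c >= n_single else 1, c)
    )


def hpw_select(effects: EffectSet, alpha: float = 0.95) -> DetectionResult:
    """Greedy simultaneous selection by highest point-wise probabilities.

    Candidates are visited in descending marginal probability. A single
    effect is skipped if a selected combined effect contains its locus; a
    combined effect is skipped if either member was selected singly or
    shares a locus with a selected combined effect. A non-excluded candidate
    is accepted only while the joint sign probability of the enlarged
    selection strictly exceeds ``alpha``; the first candidate that drops it
    to <= alpha stops the procedure.
    """
    q, sign = sign_stats(effects)
    n_single = effects.n_single
    d = effects.draws
    selected = np.zeros(d.shape[1], dtype=bool)
    singly_selected: set[int] = set()
    pair_members: set[int] = set()
    ok = np.ones(d.shape[0], dtype=bool)
    joint = 1.0
    for c in _hpw_order(q, n_single):
        if c < n_single:
            if c in pair_members:
                continue
        else:
            i = c - n_single
            j, k = int(effects.pair_j[i]), int(effects.pair_k[i])
            if (
                j in singly_selected
                or k in singly_selected
                or j in pair_members
                or k in pair_members
            ):
                continue
        cond = d[:, c] > 0 if sign[c] > 0 else d[:, c] < 0
        new_ok = ok & cond
        jp = float(new_ok.mean())
        if jp > alpha:
            selected[c] = True
            ok = new_ok
            joint = jp
            if c < n_single:
                singly_selected.add(c)
            else:
                i = c - n_single
                pair_members.add(int(effects.pair_j[i]))
                pair_members.add(int(effects.pair_k[i]))
        else:
            break
    return DetectionResult(
        labels=list(effects.labels),
        q=q,
        sign=sign,
        credible=selected,
        n_single=n_single,
        pair_j=effects.pair_j.copy(),
        pair_k=effects.pair_k.copy(),
        pair_is_sum=effects.pair_is_sum.copy(),
        alpha=alpha,
        method="hpw",
        joint_probability=joint if selected.any() else None,
    )


def types_from_flags(
    n_single: int,
    pair_j: np.ndarray,
    pair_k: np.ndarray,
    pair_is_sum: np.ndarray,
    credible: np.ndarray,
    sign: np.ndarray,
    q: np.ndarray,
) -> np.ndarray:
    """Per-locus credibility type in {0, +/-0.25, +/-0.75, +/-1}.

    A locus scores +/-1 if its own effect is credible; +/-0.75 (stronger
    member) or +/-0.25 (weaker member) if it participates in a credible
    combined effect; 0 otherwise. Member strength compares the two singles'
    own marginal sign probabilities (a tie makes the lower index the
    stronger member). For a credible difference beta_j - beta_k with sign s
    the contribution is s at locus j and -s at locus k, so a credibly
    negative difference reads as credible positivity of beta_k - beta_j.
    When several conditions hold, the largest absolute value wins; an exact
    +/- tie resolves to the positive value.
    """
    types = np.zeros(n_single)

    def consider(locus: int, val: float) -> None:
        cur = types[locus]
        if abs(val) > abs(cur) or (abs(val) == abs(cur) and val > cur):
            types[locus] = val

    for j in range(n_single):
        if credible[j]:
            consider(j, float(sign[j]))
    for i in range(pair_j.size):
        c = n_single + i
        if not credible[c]:
            continue
        j, k = int(pair_j[i]), int(pair_k[i])
        s = float(sign[c])
        s_j, s_k = (s, s) if pair_is_sum[i] else (s, -s)
        j_stronger = q[j] > q[k] or (q[j] == q[k] and j < k)
        consider(j, s_j * (0.75 if j_stronger else 0.25))
        consider(k, s_k * (0.25 if j_stronger else 0.75))
    return types


def credibility_types(result: DetectionResult) -> np.ndarray:
    """Per-locus credibility-type vector for a detection result."""
    return types_from_flags(
        result.n_single,
        result.pair_j,
        result.pair_k,
        result.pair_is_sum,
        result.credible,
        result.sign,
        result.q,
    )
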