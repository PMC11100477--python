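"""Inter-rater reliability statistics for categorical pulse labels.

Cohen's kappa corrects observed agreement for the agreement expected by
chance from the raters' marginal label frequencies; Light's kappa is the
arithmetic mean of Cohen's kappa over all unordered observer pairs. The
agreement index counts, per pulse, how many observers (reference
included) match the reference observer's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    lights_kappa: float | None = None
    degenerate: bool = False


@dataclass
class AgreementIndex:
    per_pulse: np.ndarray  # in {1..n_observers}
    per_type_mean: dict[str, float]


def cohen_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa between two label sequences.

    The label alphabet is the union of both raters' labels; a label absent
    from one rater contributes zero marginal mass. When both raters are
    constant with the same label (expected agreement 1), kappa is defined
    as 1 and the result flagged degenerate.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("label sequences must be non-empty")
    n = len(a)
    alphabet = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa = {c: a.count(c) / n for c in alphabet}
    pb = {c: b.count(c) / n for c in alphabet}
    p_e = sum(pa[c] * pb[c] for c in alphabet)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(kappa=1.0 if p_o == 1.0 else 0.0,
                           observed_agreement=p_o, expected_agreement=p_e,
                           n_items=n, degenerate=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e),
                       observed_agreement=p_o, expected_agreement=p_e, n_items=n)


def lights_kappa(labelings: dict[str, list]) -> KappaResult:
    """Light's kappa: mean pairwise Cohen's kappa over all observer pairs."""
    if len(labelings) < 2:
        raise ValueError("lights_kappa requires at least 2 observers")
    observers = list(labelings)
    lengths = {o: len(labelings[o]) for o in observers}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"observers label different numbers of items: {lengths}")
    pairwise: dict[tuple[str, str], float] = {}
    p_os, p_es = [], []
    for o1, o2 in combinations(observers, 2):
        res = cohen_kappa(labelings[o1], labelings[o2])
        pairwise[(o1, o2)] = res.kappa
        p_os.append(res.observed_agreement)
        p_es.append(res.expected_agreement)
    mean_k = float(np.mean(list(pairwise.values())))
    return KappaResult(
        kappa=mean_k, observed_agreement=float(np.mean(p_os)),
        expected_agreement=float(np.mean(p_es)),
        n_items=next(iter(lengths.values())),
        pairwise=pairwise, lights_kappa=mean_k)


def agreement_index(reference_labels, other_labelings) -> AgreementIndex:
    """Per-pulse count of observers agreeing with the reference observer.

    The reference observer counts herself, so with two other observers the
    index lies in {1, 2, 3}. Per-type means group pulses by the reference
    observer's label.
    """
    ref = list(reference_labels)
    if isinstance(other_labelings, dict):
        others = [list(v) for v in other_labelings.values()]
    else:
        others = [list(v) for v in other_labelings]
    for i, o in enumerate(others):
        if len(o) != len(ref):
            raise ValueError(
                f"observer {i} labeled {len(o)} items, reference labeled {len(ref)}")
    idx = np.array([1 + sum(o[i] == ref[i] for o in others) for i in range(len(ref))])
    per_type = {
        c: float(np.mean([idx[i] for i in range(len(ref)) if ref[i] == c]))
        for c in sorted(set(ref))
    }
    return AgreementIndex(per_pulse=idx, per_type_mean=per_type)
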