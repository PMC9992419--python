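"""EdU proliferation fractions within macrophage and fibroblast populations.

Counts are pooled over each animal's sections before fractions are
formed (small per-section counts in neonatal tendon make per-section
fractions unstable); the macrophage:fibroblast ratio of EdU-positive
fractions and a paired t-test across animals quantify the difference in
proliferation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import paired_t_report

__all__ = ["ProliferationResult", "edu_fractions", "compare_proliferation"]


@dataclass
class ProliferationResult:
    animal_id: str
    n_gfp_pos: int
    n_gfp_pos_edu: int
    n_gfp_neg: int
    n_gfp_neg_edu: int
    frac_edu_mac: float     # NaN when no GFP+ cells
    frac_edu_fib: float
    ratio: float            # NaN when either fraction undefined or 0 denom

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def edu_fractions(records_by_animal: dict[str, pd.DataFrame],
                  gfp_flag: str = "gfp_pos",
                  edu_flag: str = "edu_pos") -> list[ProliferationResult]:
    """Per-animal EdU-positive fractions, pooling all of an animal's
    in-ROI records before dividing.
    """
    results = []
    for animal, rec in records_by_animal.items():
        pos = rec[gfp_flag].to_numpy().astype(bool)
        edu = rec[edu_flag].to_numpy().astype(bool)
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        n_pos_edu = int((pos & edu).sum())
        n_neg_edu = int((~pos & edu).sum())
        f_mac = n_pos_edu / n_pos if n_pos else float("nan")
        f_fib = n_neg_edu / n_neg if n_neg else float("nan")
        if np.isfinite(f_mac) and np.isfinite(f_fib) and f_fib > 0:
            ratio = f_mac / f_fib
        else:
            ratio = float("nan")
        results.append(ProliferationResult(
            animal_id=animal, n_gfp_pos=n_pos, n_gfp_pos_edu=n_pos_edu,
            n_gfp_neg=n_neg, n_gfp_neg_edu=n_neg_edu,
            frac_edu_mac=f_mac, frac_edu_fib=f_fib, ratio=ratio))
    return results


def compare_proliferation(results: list[ProliferationResult]) -> dict:
    """Paired t-test on per-animal (macrophage, fibroblast) EdU fractions.

    Animals missing either fraction are excluded with a warning entry.
    """
    complete = [r for r in results
                if np.isfinite(r.frac_edu_mac) and np.isfinite(r.frac_edu_fib)]
    excluded = [r.animal_id for r in results if r not in complete]
    if len(complete) < 2:
        raise ValueError("need >= 2 animals with both fractions defined")
    mac = [r.frac_edu_mac for r in complete]
    fib = [r.frac_edu_fib for r in complete]
    report = paired_t_report(mac, fib)
    ratios = [r.ratio for r in complete if np.isfinite(r.ratio)]
    report.update({
        "n_animals": len(complete),
        "excluded_animals": excluded,
        "mean_frac_mac": float(np.mean(mac)),
        "mean_frac_fib": float(np.mean(fib)),
        "mean_ratio": float(np.mean(ratios)) if ratios else float("nan"),
        "ratio_of_means": (float(np.mean(mac) / np.mean(fib))
                           if np.mean(fib) > 0 else float("nan")),
    })
    return report
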