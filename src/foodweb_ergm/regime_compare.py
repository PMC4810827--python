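"""Before/after comparison of fitted ERGM parameters across a regime shift.

For every configuration shared by the two fits the percentage change is

    pct_change = 100 * (theta_after - theta_before) / |theta_before|,

i.e. the signed change relative to the magnitude of the earlier estimate
(undefined and flagged when theta_before = 0).  Configurations present in
only one model are reported separately, never silently dropped.  Fits from
different systems (e.g. offshore vs. coastal metadata regions) are refused
unless explicitly allowed, since parameter magnitudes are not comparable
across systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComparisonError

__all__ = ["RegimeComparison", "compare_fits"]


@dataclass(frozen=True)
class RegimeComparison:
    """Per-configuration before/after summary.

    ``pct_change`` entries are NaN where theta_before = 0 (flagged
    undefined).  ``only_before``/``only_after`` list configurations present
    in a single model.
    """

    names: tuple[str, ...]
    theta_before: np.ndarray
    theta_after: np.ndarray
    se_before: np.ndarray
    se_after: np.ndarray
    pct_change: np.ndarray
    sign_flip: np.ndarray
    both_significant: np.ndarray
    only_before: tuple[str, ...]
    only_after: tuple[str, ...]

    def __getitem__(self, name: str) -> float:
        return float(self.pct_change[self.names.index(name)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta_before": self.theta_before,
                "theta_after": self.theta_after,
                "se_before": self.se_before,
                "se_after": self.se_after,
                "pct_change": self.pct_change,
                "sign_flip": self.sign_flip,
                "both_significant": self.both_significant,
            },
            index=list(self.names),
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("configuration").to_csv(path)


def compare_fits(before, after, allow_cross_system: bool = False) -> RegimeComparison:
    """Percentage difference in parameter estimates from one period to the next.

    ``before`` and ``after`` are :class:`~foodweb_ergm.estimator.FitResult`
    objects sharing at least one configuration name.  Raises
    :class:`ComparisonError` when there is nothing to compare or when the
    fits belong to different systems (metadata ``region``) and
    ``allow_cross_system`` is False.
    """
    region_b = before.web_metadata.get("region")
    region_a = after.web_metadata.get("region")
    if (
        not allow_cross_system
        and region_b is not None
        and region_a is not None
        and region_b != region_a
    ):
        raise ComparisonError(
            f"refusing to compare fits across systems ({region_b!r} vs "
            f"{region_a!r}); parameter magnitudes are only comparable within "
            "one system. Pass allow_cross_system=True to override."
        )
    shared = [n for n in before.names if n in after.names]
    if not shared:
        raise ComparisonError("the two fits share no configuration names")
    only_before = tuple(n for n in before.names if n not in after.names)
    only_after = tuple(n for n in after.names if n not in before.names)

    tb = np.array([before[n] for n in shared])
    ta = np.array([after[n] for n in shared])
    sb = np.array([before.standard_errors[before.spec.index(n)] for n in shared])
    sa = np.array([after.standard_errors[after.spec.index(n)] for n in shared])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(tb != 0, 100.0 * (ta - tb) / np.abs(tb), np.nan)
    sig_b = np.array([bool(before.significant[before.spec.index(n)]) for n in shared])
    sig_a = np.array([bool(after.significant[after.spec.index(n)]) for n in shared])
    return RegimeComparison(
        names=tuple(shared),
        theta_before=tb,
        theta_after=ta,
        se_before=sb,
        se_after=sa,
        pct_change=pct,
        sign_flip=(tb * ta) < 0,
        both_significant=sig_b & sig_a,
        only_before=only_before,
        only_after=only_after,
    )
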