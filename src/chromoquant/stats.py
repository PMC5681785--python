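"""Two-sample comparisons between imaging readouts.

The comparison used throughout is the unpaired two-sample t-test, applied to
per-nucleus or per-focus readout vectors (nuclei and foci, not animals, are
the statistical units — a pseudoreplication caveat the documentation flags
but does not silently change).  Welch's unequal-variance form is the
default; pooled-variance Student's t is available behind a flag.  No
multiple-testing correction is applied: each panel-style comparison stands
alone, and reports state this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Significance star thresholds: p < 0.05, 0.01, 0.001, 0.0001.
STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    equal_var: bool = False

    @property
    def stars(self) -> str:
        """Significance stars at the four conventional thresholds
        (``*`` < 0.05 through ``****`` < 0.0001); ``ns`` otherwise."""
        n = sum(self.p_value < t for t in STAR_THRESHOLDS)
        return "*" * n if n else "ns"


def unpaired_t(
    a,
    b,
    equal_var: bool = False,
    group_a: str = "a",
    group_b: str = "b",
    metric: str = "",
) -> ComparisonResult:
    """Unpaired two-sample t-test between readout vectors *a* and *b*.

    Welch's test by default; set ``equal_var=True`` for the pooled-variance
    Student's form.  Two-sided p-value.  Degenerate input (fewer than two
    values per sample, or zero variance in both samples combined) raises
    rather than returning NaN.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each sample needs >= 2 values (got {a.size} and {b.size})"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples; t is undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(t),
        p_value=float(p),
        equal_var=equal_var,
    )
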