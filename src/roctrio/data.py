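"""Core sample containers for two-group diagnostic-test data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SampleData:
    """Continuous test results split into diseased and nondiseased groups.

    Parameters
    ----------
    diseased
        Test results of the diseased subjects (the group whose values are
        expected to be higher when the test is informative).
    nondiseased
        Test results of the nondiseased subjects.

    All values must be finite and both groups nonempty.  Variance-based
    estimators additionally require at least two subjects per group; they
    enforce that themselves.
    """

    diseased: np.ndarray
    nondiseased: np.ndarray

    def __post_init__(self) -> None:
        for name in ("diseased", "nondiseased"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"{name} group is empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} group contains non-finite values")
            object.__setattr__(self, name, arr)

    @property
    def n1(self) -> int:
        """Number of diseased subjects."""
        return self.diseased.size

    @property
    def n0(self) -> int:
        """Number of nondiseased subjects."""
        return self.nondiseased.size

    def swapped(self) -> "SampleData":
        """Return the sample with group labels exchanged."""
        return SampleData(self.nondiseased, self.diseased)

    def transformed(self, func) -> "SampleData":
        """Apply an elementwise transform to all values of both groups."""
        return SampleData(func(self.diseased), func(self.nondiseased))


@dataclass(frozen=True)
class LabeledDataset:
    """Long-format dataset: one test value and one binary status per subject."""

    values: np.ndarray
    status: np.ndarray  # boolean, True = diseased / positive
    positive_label: str = "diseased"
    negative_label: str = "nondiseased"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        status = np.asarray(self.status, dtype=bool).ravel()
        if values.size != status.size:
            raise ValueError("values and status must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        if not status.any() or status.all():
            raise ValueError("both disease statuses must be present")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "status", status)

    def to_sample(self) -> SampleData:
        """Split into a two-group :class:`SampleData`."""
        return SampleData(self.values[self.status], self.values[~self.status])
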