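"""Run configuration shared by the caller, the boundary module and the CLI.

Every tunable of the pipeline lives here with its default, so that a run can
be reproduced from the serialized config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Attributes
    ----------
    bin_size:
        Read-depth bin width in bases. 50 by default; 60 is the benchmarked
        alternative.
    smooth_window:
        Number of consecutive bins averaged by the rectangular smoother.
    merge_bins:
        Number of contiguous smoothed bins summed into one cumulative
        log2-ratio (clr) window. bin_size * merge_bins is the minimum
        reportable call length (500 nt with defaults).
    p_threshold:
        One-sided normal p-value below which a clr window is retained.
    coverage_ratio:
        Test:ref normalization for the log2 ratios; "auto" uses the ratio of
        genome-wide mean depths.
    udef_cap:
        |log2 ratio| assigned to undefined bins with no event-like defined
        neighbor to inherit from.
    udef_inherit_min:
        Minimum |log2 ratio| a defined neighbor must have to be treated as a
        same-direction event an undefined run may inherit from.
    min_mapq:
        Optional mapping-quality floor for depth computation. 0 disables it;
        the pair-wise design does not need one.
    boundary_bin:
        Bin width (bases) for anomalous-pair counting in the boundary module.
    insert_mean, insert_sd, n_sd:
        Expected library insert size, its standard deviation, and the
        tolerance multiplier: a pair is anomalous when
        |insert - insert_mean| > n_sd * insert_sd.
    boundary_tol:
        Distance (bases) within which a matched-normal boundary suppresses a
        test-sample boundary.
    snap:
        Maximum distance (bases) a call edge may move to a surviving boundary.
    max_copy_state:
        Highest amplification copy state for which a ratio window is built.
    min_boundary_count:
        Adjacent-bin ratios are only evaluated when the larger of the two
        counts reaches this floor.
    test_reciprocal:
        Also test 1/ratio against the ratio windows, so transitions out of an
        event are detected as well as transitions into it.
    margin:
        Breakpoint tolerance, as a fraction of the true event length, used
        when matching calls to truth intervals.
    seed:
        Seed for the simulation subcommands.
    """

    bin_size: int = 50
    smooth_window: int = 4
    merge_bins: int = 10
    p_threshold: float = 0.001
    coverage_ratio: float | str = "auto"
    udef_cap: float = 5.0
    udef_inherit_min: float = 0.5
    min_mapq: int = 0
    boundary_bin: int = 5000
    insert_mean: float = 250.0
    insert_sd: float = 50.0
    n_sd: float = 1.0
    boundary_tol: int = 100
    snap: int = 5000
    max_copy_state: int = 10
    min_boundary_count: int = 5
    test_reciprocal: bool = True
    margin: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_size", "smooth_window", "merge_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.coverage_ratio != "auto" and float(self.coverage_ratio) <= 0:
            raise ValueError("coverage_ratio must be positive or 'auto'")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def min_call_length(self) -> int:
        """Smallest reportable call, in bases: bin_size * merge_bins."""
        return self.bin_size * self.merge_bins

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        """Serialize verbatim (YAML) so a run can be reproduced."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
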