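"""Run configuration: the method's published operating constants.

Defaults are the printed constants of the method: the Eq.-style variant
selection thresholds (DP >= 10, FREQ > 10% for panel-vs-panel comparison;
FREQ > 0 for the permissive first identification pass), the second-pass
disambiguation rules (DP >= 20, FREQ spread > 10), the null truncation
bounds (0, 0.8), the significance cut-offs (p < 1e-3 related, p < 1e-4 same
origin), and the 200-sites-per-direction discriminative selection for
mixture regression.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    dp_min_first: float = 10
    freq_min_eq1: float = 10
    freq_min_first_pass: float = 0
    dp_min_second: float = 20
    freq_diff_min: float = 10
    a: float = 0.0
    b: float = 0.8
    alpha_related: float = 1e-3
    alpha_same: float = 1e-4
    n_per_direction: int = 200
    max_components: int = 4
    coverage_mode: str = "assume_covered"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError("need a < b")
        if not 0 < self.alpha_same < self.alpha_related < 1:
            raise ValueError("need 0 < alpha_same < alpha_related < 1")
        for name in ("dp_min_first", "dp_min_second", "n_per_direction", "max_components"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key=value config file; explicit overrides win over the file."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "coverage_mode":
                values[key] = raw
            elif key in ("n_per_direction", "max_components", "seed"):
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
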