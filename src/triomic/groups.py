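"""Treatment-group keys.

A group is one cell of the exposure design: a dose (μM) crossed with an
exposure time (hours). The default design is 2 doses x 3 times, but nothing
below assumes that.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import FormatError

_GROUP_RE = re.compile(r"^(?P<dose>\d+(?:\.\d+)?)uM-(?P<time>\d+(?:\.\d+)?)h$")


def _fmt_num(x: float) -> str:
    """Render 100.0 as '100' but keep genuine fractions."""
    return str(int(x)) if float(x).is_integer() else str(x)


@dataclass(frozen=True, order=True)
class GroupKey:
    """One treatment group, identified by dose in μM and exposure time in hours."""

    dose: float
    time: float

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.time <= 0:
            raise ValueError(f"dose and time must be positive, got {self.dose}, {self.time}")
        # normalise to float so GroupKey(100, 12) == GroupKey(100.0, 12.0)
        object.__setattr__(self, "dose", float(self.dose))
        object.__setattr__(self, "time", float(self.time))

    def __str__(self) -> str:
        return f"{_fmt_num(self.dose)}uM-{_fmt_num(self.time)}h"

    @classmethod
    def parse(cls, text: str) -> "GroupKey":
        m = _GROUP_RE.match(text.strip())
        if not m:
            raise FormatError(f"cannot parse group key {text!r}; expected '<dose>uM-<time>h'")
        return cls(float(m["dose"]), float(m["time"]))


def default_groups(doses=(100.0, 200.0), times=(12.0, 24.0, 48.0)) -> list[GroupKey]:
    """The full-factorial group list in canonical (dose, time) order."""
    return [GroupKey(d, t) for d in sorted(doses) for t in sorted(times)]
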