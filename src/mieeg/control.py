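"""Mapping classifier decisions to device commands with threshold gating.

Each of the six imagery classes maps to one single-bit instruction byte
for the controlled cart.  To suppress spurious classifications, an
accumulator emits an instruction only after the same class has been
seen ``threshold`` times in a row; the count resets on a class change
and after each emission, so threshold 1 passes everything through and
threshold 2 requires "the same instruction twice in a row".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: class id -> (task, function, instruction byte)
COMMAND_MAP: dict[int, tuple[str, str, int]] = {
    1: ("L-fist", "left", 0x20),
    2: ("R-fist", "right", 0x10),
    3: ("L-feet", "backward", 0x08),
    4: ("R-feet", "forward", 0x04),
    5: ("L-thumb", "stop", 0x02),
    6: ("R-thumb", "start", 0x01),
}


def class_to_instruction(class_id: int) -> int:
    """Instruction byte of one imagery class (distinct powers of two)."""
    try:
        return COMMAND_MAP[int(class_id)][2]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"unknown class id {class_id!r}; expected 1..6") \
            from None


def class_function(class_id: int) -> str:
    return COMMAND_MAP[int(class_id)][1]


@dataclass
class Mode:
    """A cart operating mode: speed is metadata only (no cart simulated)."""

    speed_cm_s: float = 2.0
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass
class ThresholdAccumulator:
    """Consecutive-identical counter that gates instruction emission."""

    threshold: int = 1
    last_class: int | None = None
    count: int = 0
    emitted: list[tuple[int, int]] = field(default_factory=list)
    _step: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")

    def feed(self, class_id: int) -> int | None:
        """Feed one classification; returns the instruction byte if the
        run length reaches the threshold, else None."""
        byte = class_to_instruction(class_id)
        self._step += 1
        if class_id == self.last_class:
            self.count += 1
        else:
            self.last_class = class_id
            self.count = 1
        if self.count >= self.threshold:
            self.count = 0          # reset after emission
            self.last_class = class_id
            self.emitted.append((self._step, byte))
            return byte
        return None


def feed(acc: ThresholdAccumulator, class_id: int) -> int | None:
    return acc.feed(class_id)


def run_session(decisions, mode: Mode | None = None) -> pd.DataFrame:
    """Run a decision stream through the accumulator.

    Returns a log with one row per input: step, class, emitted flag,
    and the instruction as integer and hex string.  Per-function counts
    are available via :func:`session_counts`.
    """
    mode = mode or Mode()
    acc = ThresholdAccumulator(threshold=mode.threshold)
    rows = []
    for step, cls in enumerate(decisions, start=1):
        byte = acc.feed(cls)
        rows.append({
            "step": step,
            "class": int(cls),
            "task": COMMAND_MAP[int(cls)][0],
            "emitted": byte is not None,
            "instruction": byte if byte is not None else 0,
            "instruction_hex": f"0x{byte:02X}" if byte is not None else "",
        })
    return pd.DataFrame(rows, columns=["step", "class", "task", "emitted",
                                       "instruction", "instruction_hex"])


def session_counts(log: pd.DataFrame) -> dict[str, int]:
    """Number of emitted instructions per control function, plus total."""
    counts = {fn: 0 for _, fn, _ in COMMAND_MAP.values()}
    emitted = log.loc[log["emitted"].astype(bool)]
    for cls in emitted["class"]:
        counts[class_function(cls)] += 1
    counts["total"] = int(emitted.shape[0])
    return counts
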