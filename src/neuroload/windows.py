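"""Epoching of task and rest blocks into labeled analysis windows.

Task blocks (44 s) are cut with half-window stride; for 10 s and 20 s
windows an extra window snapped to the block end is appended, which yields
the characteristic counts 16/8/4/2 windows per task block at lengths
5/10/20/25 s.  Rest blocks (25 s) follow per-length rules producing
5/4/2/1 windows.  Instruction blocks yield no windows.  Windows never
cross block boundaries, so every window carries a single class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .types import Block, Window

WINDOW_LENGTHS = (5.0, 10.0, 20.0, 25.0)


@dataclass(frozen=True)
class WindowPolicy:
    """Cutting rules for one window length.

    ``task_stride`` defaults to half the window length.  ``task_end_anchor``
    appends a final task window flush with the block end when the strided
    grid leaves a remainder (applied at 10 s and 20 s).  ``rest_rule`` is
    one of ``"no_overlap"``, ``"half_stride"``, ``"start_end"`` (one window
    at each block edge), or ``"single"``.
    """

    window_len: float
    task_stride: float
    task_end_anchor: bool
    rest_rule: str

    @classmethod
    def default(cls, window_len: float) -> "WindowPolicy":
        rules = {
            5.0: ("no_overlap", False),
            10.0: ("half_stride", True),
            20.0: ("start_end", True),
            25.0: ("single", False),
        }
        if float(window_len) not in rules:
            raise ValueError(f"window_len must be one of {WINDOW_LENGTHS}")
        rest_rule, anchor = rules[float(window_len)]
        return cls(window_len=float(window_len),
                   task_stride=float(window_len) / 2.0,
                   task_end_anchor=anchor,
                   rest_rule=rest_rule)


def _strided_starts(t0: float, t1: float, length: float, stride: float) -> list[float]:
    starts = []
    t = t0
    while t + length <= t1 + 1e-9:
        starts.append(t)
        t += stride
    return starts


def _cut_task(block: Block, policy: WindowPolicy) -> list[float]:
    starts = _strided_starts(block.t_start, block.t_end,
                             policy.window_len, policy.task_stride)
    if policy.task_end_anchor:
        end_start = block.t_end - policy.window_len
        if not starts or end_start > starts[-1] + 1e-9:
            starts.append(end_start)
    return starts


def _cut_rest(block: Block, policy: WindowPolicy) -> list[float]:
    L = policy.window_len
    if policy.rest_rule == "no_overlap":
        return _strided_starts(block.t_start, block.t_end, L, L)
    if policy.rest_rule == "half_stride":
        return _strided_starts(block.t_start, block.t_end, L, L / 2.0)
    if policy.rest_rule == "start_end":
        starts = [block.t_start]
        end_start = block.t_end - L
        if end_start > block.t_start + 1e-9:
            starts.append(end_start)
        return starts
    if policy.rest_rule == "single":
        return [block.t_start] if block.duration + 1e-9 >= L else []
    raise ValueError(f"unknown rest rule {policy.rest_rule!r}")


def make_windows(blocks: list[Block],
                 policy: WindowPolicy | float) -> list[Window]:
    """Cut labeled windows out of task and rest blocks.

    ``policy`` may be a :class:`WindowPolicy` or a bare window length, in
    which case the default per-length rules apply.  Blocks shorter than the
    window length contribute no windows (with a warning).
    """
    if not isinstance(policy, WindowPolicy):
        policy = WindowPolicy.default(float(policy))
    out: list[Window] = []
    for bi, block in enumerate(blocks):
        if block.kind == "instruction":
            continue
        if block.duration + 1e-9 < policy.window_len:
            warnings.warn(
                f"block {bi} ({block.kind}, {block.duration:g} s) shorter "
                f"than {policy.window_len:g} s window; skipped"
            )
            continue
        starts = (_cut_task(block, policy) if block.kind == "task"
                  else _cut_rest(block, policy))
        label = block.label if block.kind == "task" else "rest"
        for t in starts:
            out.append(Window(label=label, t_start=t,
                              t_end=t + policy.window_len, source_block=bi))
    return out
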