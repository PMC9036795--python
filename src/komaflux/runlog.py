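"""Lightweight run log: timestamped messages plus auditable filter counts.

Filtering operations record how many records were read, kept, and dropped so
that per-chromosome "# m" style counts in reports can be audited against the
log afterwards.
"""

from __future__ import annotations

import datetime
import logging

logger = logging.getLogger("komaflux")


class RunLog:
    def __init__(self) -> None:
        self.messages: list[tuple[str, str, str]] = []  # (timestamp, level, message)
        self.counts: dict[str, int] = {}

    def log(self, message: str, level: str = "INFO") -> None:
        ts = datetime.datetime.now().isoformat(timespec="seconds")
        self.messages.append((ts, level, message))
        logger.log(getattr(logging, level, logging.INFO), message)

    def record_filter(self, name: str, n_in: int, n_kept: int) -> None:
        self.counts[f"{name}.read"] = n_in
        self.counts[f"{name}.kept"] = n_kept
        self.counts[f"{name}.dropped"] = n_in - n_kept
        self.log(f"{name}: read {n_in}, kept {n_kept}, dropped {n_in - n_kept}")

    def warn(self, message: str) -> None:
        self.log(message, level="WARNING")
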