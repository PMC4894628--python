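"""Package logger with per-stage INFO timing."""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager

logger = logging.getLogger("tumorcbir")


@contextmanager
def stage_timer(stage: str):
    """Log the wall time of a pipeline stage at INFO level."""
    t0 = time.perf_counter()
    logger.info("%s: started", stage)
    try:
        yield
    finally:
        logger.info("%s: done in %.2fs", stage, time.perf_counter() - t0)
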