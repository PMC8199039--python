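"""End-to-end run processing: segmentation -> exclusion -> enrichment -> labels.

Thin orchestration over the preprocess, enrich and classify modules, shared
by the command-line interface and the test-bench.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np

from .config import Config
from .enrich import edge_angle_vector, enrich_turn
from .preprocess import attach_mean_speeds, detect_turn_boundaries, filter_turns
from .types import EnrichedTurn, RawRun

log = logging.getLogger(__name__)


def process_run(run: RawRun, config: Optional[Config] = None,
                labels: Optional[dict] = None) -> List[EnrichedTurn]:
    """Turn one raw run into enriched, labelled turns.

    ``labels`` maps ``(run_id, turn_index)`` to a style label that
    overrides the classifier; ``turn_index`` counts retained turns from 0.
    """
    config = config or Config()
    labels = labels or {}
    stream = run.left if config.segmentation.source_boot == "left" else run.right
    gap_times = tuple(float(stream.timestamps[i]) for i in stream.gap_indices)
    segments = detect_turn_boundaries(
        stream.timestamps, stream.roll_rate_dps, config.segmentation,
        gap_times=gap_times)
    attach_mean_speeds(segments, run.gnss)
    retained = filter_turns(segments, mad_rule=config.filter.mad_rule)
    log.info("%s: %d turn(s) detected, %d retained",
             run.run_id, len(segments), len(retained))
    if not retained:
        return []

    edges = [edge_angle_vector(run, seg, config) for seg in retained]

    def opposite(idx: int, step: int) -> Optional[np.ndarray]:
        j = idx + step
        while 0 <= j < len(retained):
            if retained[j].direction != retained[idx].direction:
                return edges[j]
            j += step
        return None

    turns = []
    for i, seg in enumerate(retained):
        turns.append(enrich_turn(
            run, seg,
            neighbours={"prev_opposite": opposite(i, -1),
                        "next_opposite": opposite(i, +1)},
            style_label=labels.get((run.run_id, i)),
            config=config, edge=edges[i], turn_index=i))
    return turns
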