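"""Combined expression/copy-number gene signature per progression task.

The combined signature intersects the differential-expression calls with the
recurrent copy-number calls: genes both up-regulated and amplified, and genes
both down-regulated and deleted.  These two sets define the COMB feature
space and the gene axes of the dissimilarity representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombinedSignature:
    """Up-amplified and down-deleted gene sets for one task."""

    up_amplified: frozenset[str]
    down_deleted: frozenset[str]
    task: str | None = None

    @property
    def genes(self) -> frozenset[str]:
        return self.up_amplified | self.down_deleted

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up_amplified") for g in sorted(self.up_amplified)]
        rows += [(g, "down_deleted") for g in sorted(self.down_deleted)]
        return pd.DataFrame(rows, columns=["gene_id", "direction"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def combine_signature(
    up_set,
    down_set,
    amplified_set,
    deleted_set,
    task: str | None = None,
) -> CombinedSignature:
    """Intersect DE calls with recurrent CNA calls.

    A gene landing in both directions (possible only with pathological
    inputs, e.g. up-regulated and down-regulated at once) is removed from
    both sets and logged.
    """
    up_amplified = frozenset(up_set) & frozenset(amplified_set)
    down_deleted = frozenset(down_set) & frozenset(deleted_set)
    clash = up_amplified & down_deleted
    if clash:
        logger.warning(
            "%d genes fell in both signature directions and were dropped: %s",
            len(clash), sorted(clash),
        )
        up_amplified -= clash
        down_deleted -= clash
    if not up_amplified and not down_deleted:
        logger.warning("combined signature is empty for task %s", task)
    return CombinedSignature(
        up_amplified=up_amplified, down_deleted=down_deleted, task=task
    )
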