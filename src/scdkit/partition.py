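"""Node partition: every node carries exactly one community label."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Partition:
    """Assignment of every node to exactly one community.

    Labels are arbitrary hashables (strings survive file round trips
    verbatim); ``k`` is the number of distinct labels actually present.
    """

    node_ids: list[str]
    labels: list

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.labels):
            raise ValueError("node_ids and labels must be parallel")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node identifiers in partition")

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def to_dict(self) -> dict[str, object]:
        return dict(zip(self.node_ids, self.labels))

    def aligned_codes(self, node_order: list[str]) -> np.ndarray:
        """Integer label codes aligned to an external node ordering."""
        mapping = self.to_dict()
        missing = [u for u in node_order if u not in mapping]
        if missing:
            raise ValueError(f"nodes missing a label: {missing[:10]}")
        labs = [mapping[u] for u in node_order]
        _, codes = np.unique(np.asarray(labs, dtype=object), return_inverse=True)
        return codes.astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.to_dict() == other.to_dict()
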