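"""Canonical scalp montage used as network nodes.

The 21 classical 10-20 electrode sites are the node set of every network
in this package; restricting to these widely spaced sites is the usual
cheap mitigation of volume conduction in sensor-space connectivity.
"""

from __future__ import annotations

from itertools import combinations

#: The 21 canonical 10-20 electrodes, in the fixed serialization order
#: used for every adjacency matrix in the package.
CANONICAL_21: tuple[str, ...] = (
    "FP1", "FP2", "FPz", "F7", "F3", "F4", "Fz", "F8",
    "T7", "C3", "C4", "Cz", "T8",
    "P7", "P3", "P4", "Pz", "P8",
    "O1", "O2", "Oz",
)

#: Medial fronto-parietal sites used as a default-mode-network proxy:
#: all pairs among these six electrodes form the default planted edge set
#: of the synthetic cohort.
DMN_PROXY_NODES: tuple[str, ...] = ("FPz", "Fz", "Cz", "Pz", "P3", "P4")

#: Frontal spatial profile of ocular (blink) artifacts: relative amplitude
#: per electrode, largest at the frontopolar sites and decaying posteriorly.
OCULAR_TOPOGRAPHY: dict[str, float] = {
    "FP1": 1.0, "FP2": 1.0, "FPz": 1.0,
    "F7": 0.45, "F3": 0.5, "F4": 0.5, "Fz": 0.55, "F8": 0.45,
    "T7": 0.12, "C3": 0.2, "C4": 0.2, "Cz": 0.25, "T8": 0.12,
    "P7": 0.05, "P3": 0.08, "P4": 0.08, "Pz": 0.1, "P8": 0.05,
    "O1": 0.03, "O2": 0.03, "Oz": 0.03,
}


def dmn_proxy_edges(nodes: tuple[str, ...] = DMN_PROXY_NODES) -> tuple[tuple[str, str], ...]:
    """All unordered pairs among ``nodes`` — the default planted edge set."""
    return tuple(combinations(nodes, 2))


def validate_labels(labels: list[str] | tuple[str, ...]) -> None:
    """Raise ``ValueError`` for duplicate or unknown electrode labels."""
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels")
    unknown = [lab for lab in labels if lab not in CANONICAL_21]
    if unknown:
        raise ValueError(
            f"unknown electrode label(s) {unknown}; expected a subset of the "
            f"canonical 21: {', '.join(CANONICAL_21)}"
        )
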