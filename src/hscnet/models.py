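"""Built-in network models.

The HSC model ships as a packaged ``.bnet`` file together with a
two-column table mapping the ASCII-normalized node identifiers used in
the file to the human-readable display names used in reports.
"""

from __future__ import annotations

from importlib import resources

from .network import BooleanNetwork, parse_network


def _read_text(filename: str) -> str:
    return resources.files("hscnet.data").joinpath(filename).read_text("utf-8")


def hsc_display_names() -> dict[str, str]:
    """Canonical ASCII identifier → display name for the HSC model."""
    mapping = {}
    for line in _read_text("hsc_names.tsv").splitlines():
        if line.strip():
            canonical, display = line.split("\t")
            mapping[canonical] = display
    return mapping


def hsc_model() -> BooleanNetwork:
    """The hematopoietic stem cell quiescence/activation network.

    36 nodes, two of them niche inputs (external quiescence and external
    cycling stimuli) modeled as self-regulating nodes.  Under synchronous
    updates the unperturbed model has exactly four fixed-point attractors,
    one per combination of the two inputs.
    """
    net = parse_network(_read_text("hsc.bnet"), display_names=hsc_display_names())
    return net
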