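"""Packaged gene sets.

The IEG panel shipped here is a synthetic stand-in: a curated list of 103
canonical mouse immediate-early / activity-regulated gene symbols assembled
for this package (see the header of ``resources/ieg_panel_103_synthetic.tsv``).
Analyses of real data should substitute the panel actually used for that
study via :func:`iegactivity.io.read_gene_set`.
"""

from __future__ import annotations

from importlib import resources

from .data import GeneSet

_PANEL_FILE = "ieg_panel_103_synthetic.tsv"


def load_ieg_panel() -> GeneSet:
    """The packaged 103-gene IEG panel (synthetic stand-in, see module docstring)."""
    text = (
        resources.files("iegactivity.resources").joinpath(_PANEL_FILE).read_text()
    )
    symbols = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneSet(name="ieg_panel_103", symbols=tuple(symbols))
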