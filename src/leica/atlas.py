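"""Packaged AAL region labels.

The full Anatomical Automatic Labeling parcellation has 116 regions; the
standard whole-cortex analysis drops the 26 cerebellar regions (9 bilateral
cerebellar lobule pairs plus 8 vermis divisions), leaving the 90 cortical
and subcortical regions, here in symmetrical right-then-left order.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["aal_labels", "is_cerebellar"]


def is_cerebellar(label: str) -> bool:
    """True for cerebellar lobule and vermis labels."""
    return "Cerebellum" in label or "Vermis" in label


def aal_labels(include_cerebellum: bool = False) -> list[str]:
    """Return the packaged AAL label list.

    With ``include_cerebellum=False`` (default) the 26 cerebellar labels
    are removed, leaving the 90 cortical and subcortical regions.
    """
    text = resources.files("leica.data").joinpath("aal116.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if include_cerebellum:
        return labels
    return [lb for lb in labels if not is_cerebellar(lb)]
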