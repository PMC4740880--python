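"""Re-export of the marker-map types (kept here for simulate-side imports)."""

from riphewas.markers import COLUMNS, MarkerMap, random_marker_map

__all__ = ["COLUMNS", "MarkerMap", "random_marker_map"]
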