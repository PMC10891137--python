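"""Post-allocation overlays and thematic refinement.

Glacier extent is better predicted by mechanistic ice models than by demand
extrapolation, so allocated glacier cells are recoded to bare land and the
map is then overlaid with externally supplied glacier and glacial-lake
masks.  Static aggregate classes are finally resolved to their
fine-thematic-resolution counterparts.
"""

from __future__ import annotations

import numpy as np

from .raster_io import ClassCodebook, ClassDef, GridAlignmentError, LULCMap

__all__ = [
    "replace_class",
    "overlay_masks",
    "fine_codebook",
    "refine_static_classes",
]


def replace_class(lulc: LULCMap, source_class: int, target_class: int) -> LULCMap:
    """Recode every ``source_class`` cell to ``target_class``."""
    for cid in (source_class, target_class):
        if cid not in lulc.codebook:
            raise KeyError(f"unknown class id {cid}")
    codes = np.where(lulc.codes == source_class, target_class, lulc.codes)
    return LULCMap(lulc.grid, codes, lulc.codebook, lulc.valid_mask.copy())


def overlay_masks(
    lulc: LULCMap,
    glacier_mask: np.ndarray | None = None,
    lake_mask: np.ndarray | None = None,
    *,
    glacier_class: int | None = None,
    lake_class: int | None = None,
) -> LULCMap:
    """Stamp external glacier/lake extents onto the map.

    Lake wins over glacier on overlapping cells: new lakes form in
    deglaciated terrain.  Mask cells outside the valid area are ignored.
    """
    codes = lulc.codes.copy()
    if glacier_class is None and glacier_mask is not None:
        glacier_class = lulc.codebook.id_of("Glacier")
    if lake_class is None and lake_mask is not None:
        lake_class = lulc.codebook.id_of("Lakes")
    for mask, cid in ((glacier_mask, glacier_class), (lake_mask, lake_class)):
        if mask is None:
            continue
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != lulc.grid.shape:
            raise GridAlignmentError("overlay mask is not aligned to the grid")
        codes = np.where(mask & lulc.valid_mask, cid, codes)
    return LULCMap(lulc.grid, codes, lulc.codebook, lulc.valid_mask.copy())


def fine_codebook(book: ClassCodebook) -> ClassCodebook:
    """Fine-thematic codebook: modelled classes plus each static fine code."""
    classes = [c for c in book.classes if c.modelled]
    for agg in book.classes:
        if not agg.static:
            continue
        for fid in agg.fine_ids:
            name = agg.name if len(agg.fine_ids) == 1 else f"{agg.name} ({fid})"
            classes.append(ClassDef(fid, name, modelled=False, static=True))
    return ClassCodebook(tuple(classes), dict(book.aliases))


def refine_static_classes(lulc: LULCMap, subclass_map: np.ndarray) -> LULCMap:
    """Resolve static aggregate codes to fine-resolution codes.

    ``subclass_map`` must supply, for every static cell, a fine code drawn
    from that aggregate's allowed set; modelled-class cells are unchanged.
    The result uses the fine codebook.
    """
    subclass_map = np.asarray(subclass_map)
    if subclass_map.shape != lulc.grid.shape:
        raise GridAlignmentError("subclass map is not aligned to the grid")
    codes = lulc.codes.copy()
    for agg in lulc.codebook.classes:
        if not agg.static:
            continue
        cells = (lulc.codes == agg.id) & lulc.valid_mask
        fine = subclass_map[cells]
        bad = ~np.isin(fine, agg.fine_ids)
        if bad.any():
            rr, cc = np.nonzero(cells)
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"cell ({rr[i]}, {cc[i]}): fine code {int(fine[i])} is not a "
                f"sub-class of {agg.name!r} (allowed: {list(agg.fine_ids)})")
        codes[cells] = fine
    return LULCMap(lulc.grid, codes, fine_codebook(lulc.codebook),
                   lulc.valid_mask.copy())
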