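"""Map a planted activation pattern into grid space and recover its position.

Plants a hand-like Gaussian hotspot at the canonical somatotopic position
(central sulcus, two thirds up the dorsoventral axis), smooths it on the
surface, averages it into tiles, orients the map (dorsal up, precentral
left), and compares the peak tile's true parametric position against the
planted center using the generator's ground truth.
"""

import numpy as np

from cgrid import (
    Hotspot,
    LabelDialect,
    SubjectSpec,
    build_cgrid,
    extract_roi_halves,
    extract_smx_borders,
    make_activation,
    make_subject,
    map_vertex_values_to_grid,
    orient_grid,
    parametric_lookup,
    smooth_vertex_values,
)

subject = make_subject(SubjectSpec(seed=3))
dialect = LabelDialect.freesurfer_aparc()
griddef = build_cgrid(subject.mesh, extract_smx_borders(subject.mesh, dialect))

hotspot = Hotspot(s=0.5, t=0.67, amplitude=1.0, width=0.10, body_part="hand")
field = make_activation(subject, hotspots=(hotspot,), noise_sd=0.1)
field = smooth_vertex_values(field, subject.mesh, fwhm=6.0)

cmap = orient_grid(map_vertex_values_to_grid(field, griddef))
masked = np.where(cmap.mask, cmap.values, -np.inf)
row, col = np.unravel_index(np.argmax(masked), cmap.shape)
print(f"peak tile (row, col) = ({row}, {col}) of {cmap.shape};"
      " row 0 is dorsal, columns run precentral -> postcentral")

m1, s1 = extract_roi_halves(cmap)
print(f"peak lies in {'M1' if col < cmap.shape[1] // 2 else 'S1'}"
      f" (M1 = left half, S1 = right half)")

# ground truth check: definition rows run ventral -> dorsal
center = griddef.tile_polygon(griddef.n_rows - 1 - row, col).mean(axis=0)
s, t = parametric_lookup(subject)([center])[0]
err = np.hypot((s - hotspot.s) * griddef.m_columns,
               (t - hotspot.t) * griddef.n_rows)
print(f"planted center (s, t) = ({hotspot.s:.2f}, {hotspot.t:.2f});"
      f" recovered ({s:.3f}, {t:.3f}) -> error {err:.2f} tiles")
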