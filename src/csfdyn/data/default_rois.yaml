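# Default DTI-ALPS ROI configuration for MNI152 template space.
#
# Four spherical ROIs (radius 2.5 mm) at the level of the lateral-ventricle
# body: two on the projection fibres (corona radiata, y-dominant diffusion)
# and two on the association fibres (superior longitudinal fasciculus,
# z-dominant diffusion), one per hemisphere.  Coordinates are the commonly
# published lateral-ventricle-level placements; verify against your own
# template registration before trusting absolute values, and prefer
# supplying a site-specific ROI file.
rois:
  - {label: projection, hemisphere: left,  center_mm: [-26.0, -14.0, 28.0], radius_mm: 2.5}
  - {label: projection, hemisphere: right, center_mm: [26.0, -14.0, 28.0], radius_mm: 2.5}
  - {label: association, hemisphere: left,  center_mm: [-36.0, -14.0, 28.0], radius_mm: 2.5}
  - {label: association, hemisphere: right, center_mm: [36.0, -14.0, 28.0], radius_mm: 2.5}
# in-plane displacement search bound (voxels) and WM-probability exclusion
search_bound: 2
wm_threshold: 0.90
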