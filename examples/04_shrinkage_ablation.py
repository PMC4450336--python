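"""With/without intensity modification on a shrinking-tumor study.

Generates the standard synthetic study (tumor volume factor 0.67, lethal
in-tumor dose, anatomic background deformation), runs the full pipeline
twice — with and without the intensity-modification stage — and compares
the tumor Dice overlap against the known posttreatment contour.
Takes about a minute.
"""

from shrinkreg import PipelineConfig, PreprocessParams, make_shrinkage_study, run_pipeline

st = make_shrinkage_study(seed=3)
pre = PreprocessParams(couch_box=st.couch_box)

scores = {}
for use_imp in (True, False):
    res = run_pipeline(
        st.posttreatment,
        st.planning,
        st.dose,
        st.tumor,
        truth_mask=st.shrunken_tumor,
        config=PipelineConfig(preprocess=pre, use_imp=use_imp),
    )
    scores[use_imp] = res
    label = "with IMP   " if use_imp else "without IMP"
    print(f"{label}: rigid DSC {res.dsc_rigid:.1f}%  ->  deformable DSC {res.dsc_deformable:.1f}%")

gap = scores[True].dsc_deformable - scores[False].dsc_deformable
print(f"intensity modification changes the tumor DSC by {gap:+.1f} points "
      f"(the planning tumor boundary moves by under a voxel at this volume factor)")
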