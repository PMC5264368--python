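# End-to-end synthetic run: omnibus decomposition followed by simultaneous
# VBCM of the factor scores, with and without the lesion-volume covariate.
stages: [omnibus_pca, vbcm_factors]
synthetic: true
seed: 1
output_dir: pcavbcm_out
vbcm:
  p_voxel: 0.005
  fwe_alpha: 0.05
  connectivity: 26
  n_perm: 200
  seed: 1
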