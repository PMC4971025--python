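# Default automated correction protocol: the two fully automatic cleanup
# stages. Stage 2 eradicates small islands of the catch-all suspicious
# label (face connectivity breaks dust into small groups; no dilation so
# islands close to other dust are still cleaned; force so every island
# moves). Stage 4 removes isolated dust from all remaining labels
# (dilation-gated isolation so viable island clusters survive; labels with
# legitimately disconnected bodies, e.g. CSF, should be excluded).
suspicious_label: 999
stages:
  - name: stage2-suspicious-dust
    max_island_voxel_count: 6
    connectivity: face
    use_dilation: false
    force_relabel: true
    review: [suspicious]        # resolved to the suspicious label ID
    exclude: []
  - name: stage4-isolated-dust
    max_island_voxel_count: 5
    connectivity: full
    use_dilation: true
    force_relabel: true
    review: all
    exclude: [csf]              # resolved to user-supplied CSF-like labels
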