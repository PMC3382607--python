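# Phenotypic definitions of human PBMC subsets used for boolean gating.
# Predicates: "+" above the channel's positivity cutoff, "-" at or below it,
# "hi"/"lo" above/below the channel's secondary cutoff (both CD52-positive
# senses of "lo" are still above the positivity cutoff).
#
# The NK rows carry CD11c-/CD14-/CD123- in addition to their lineage markers
# so that every pair of definitions is logically disjoint under the panel —
# the sequential manual gating they transcribe implies these negations.
subsets:
  - name: Naive-B
    lineage: lymphoid
    predicates: {CD3: "-", CD19: "+", CD27: "-"}
  - name: Memory-B
    lineage: lymphoid
    predicates: {CD3: "-", CD19: "+", CD27: "+"}
  - name: CD4-Naive
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "+", CD8: "-", CD45RA: "+", CD27: "+"}
  - name: CD4-CM
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "+", CD8: "-", CD45RA: "-", CD27: "+"}
  - name: CD4-EM
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "+", CD8: "-", CD45RA: "-", CD27: "-"}
  - name: CD4-Effector
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "+", CD8: "-", CD45RA: "+", CD27: "-"}
  - name: CD8-Naive
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "-", CD8: "+", CD45RA: "+", CD27: "+"}
  - name: CD8-CM
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "-", CD8: "+", CD45RA: "-", CD27: "+"}
  - name: CD8-EM
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "-", CD8: "+", CD45RA: "-", CD27: "-"}
  - name: CD8-Effector
    lineage: lymphoid
    predicates: {CD19: "-", CD3: "+", CD4: "-", CD8: "+", CD45RA: "+", CD27: "-"}
  - name: CD16lo-NK
    lineage: lymphoid
    predicates: {CD3: "-", CD19: "-", CD56: "hi", CD16: "lo",
                 CD11c: "-", CD14: "-", CD123: "-"}
  - name: CD16hi-NK
    lineage: lymphoid
    predicates: {CD3: "-", CD19: "-", CD56: "lo", CD16: "hi",
                 CD11c: "-", CD14: "-", CD123: "-"}
  - name: CD16pos-Mono
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "+", CD11c: "+", CD14: "+", CD16: "+"}
  - name: CD16neg-Mono
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "+", CD11c: "+", CD14: "+", CD16: "-"}
  - name: CD16pos-mDC
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "+", CD11c: "+", CD14: "-", CD16: "+"}
  - name: CD16neg-mDC
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "+", CD11c: "+", CD14: "-", CD16: "-"}
  - name: pDC
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "+", CD11c: "-", CD14: "-",
                 CD123: "+", BDCA2: "+"}
  - name: Basophils
    lineage: myeloid
    predicates: {CD3: "-", CD19: "-", HLADR: "-", CD11c: "-", CD14: "-", CD123: "+"}
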