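# Example configuration for `oem run` / `oem sweep-conc` / `oem sweep-q`.
# A pure acetone-like odorant (one dominant receptor) at 100 ppm through
# the full antenna -> antennal lobe -> calyx cascade.

dt: 1.0e-5          # shared integration step (s)
n_receptors: 23     # receptor types / AL channels
n_kcs: 500          # Kenyon cells
q: 6                # PN inputs (dendritic claws) per KC
n_osns: 1           # OSNs per receptor type (pooled per channel)
graph_seed: 1
noise_seed: 0
kc_threshold: 0.5   # active-KC dendritic-output threshold
apl_feedback: true

stimulus:
  t_on: 0.3         # odor onset (s)
  t_off: 1.3        # odor offset (s)
  tail: 0.2         # post-offset simulated tail (s)

odorants:
  - name: acetone_like
    profile: sparse-1   # one dominant receptor; sparse-3 / broad also valid
    seed: 7

components:
  - odorant: acetone_like
    amplitude_ppm: 100.0

# Optional per-block parameter overrides, e.g.:
# params:
#   coreceptor: {i_max: 50.0}
#   kc_dendrite: {kappa1: 25.0}
#   apl: {alpha1: 0.001, beta1: 10.0}
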