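"""Robustness to missing data: hide a growing share of the known network.

Per repeat, a fraction of the known associations is masked; the
recovery must rank the hidden entries above the true unknowns.  The
mean AUC over 20 repeats should decline as the mask ratio grows —
less training signal, harder completion — while staying well above
chance at moderate ratios.
"""

from ilrmr import SynthConfig, generate_network, mask_experiment

assoc, sim_fun, sim_phe, fams, _ = generate_network(
    SynthConfig(m=20, n=12, rank=2, density=0.15, seed=3)
)
print(f"{assoc.n_known()} known associations; 20 repeats per ratio\n")
print("mask ratio   mean AUC")
for ratio in (0.1, 0.3, 0.6):
    rep = mask_experiment(assoc, sim_fun, sim_phe, fams,
                          mask_ratio=ratio, n_repeats=20, seed=1)
    print(f"   {ratio:.1f}       {rep.auc:.4f}")
print("\n(AUC should be highest at ratio 0.1 and lowest at 0.6)")
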