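"""The side-branch ablation experiment: remove diagonals from a stenosed
LAD-like tree and watch trunk wall shear inflate.

Four pulsatile simulations (3, 2, 1, 0 side branches) share the same
inlet velocity (matched inflow at the ostium).  Removing branches forces
all flow through the trunk, so the trunk-averaged time-averaged
endothelial shear stress (TAESS) rises monotonically — single-conduit
models overestimate shear.  Takes a few minutes on one CPU.
"""

from coroflow.pipeline import run_branch_ablation

result = run_branch_ablation(period_s=0.1, samples_per_cycle=12)

print(f"{'model':>6} {'trunk TAESS (Pa)':>17} {'0D prediction':>14} "
      f"{'trunk outflow (ml/s)':>21}")
for k in (3, 2, 1, 0):
    m = result["models"][f"LAD{k}"]
    print(f"LAD {k:>2} {m['trunk_mean_taess_pa']:>17.2f} "
          f"{result['predicted_0d'][f'LAD{k}']:>14.2f} "
          f"{m['trunk_outflow_mls']:>21.3f}")

t3 = result["models"]["LAD3"]["trunk_mean_taess_pa"]
t0 = result["models"]["LAD0"]["trunk_mean_taess_pa"]
print(f"\nbranch-free / complete TAESS ratio: {t0/t3:.2f}x — omitting side "
      f"branches overestimates trunk shear; the 0D resistor network "
      f"predicts the same ordering")
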