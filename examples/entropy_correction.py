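"""Standard-state entropy correction and binding free-energy composition.

Samples bound-ion positions from a 3-D Gaussian with σ = 0.3 Å, estimates
ΔG_tr = −k_BT·ln[(2πe)^{3/2}σxσyσz/V₀] from the samples, and composes a
total binding free energy ΔG_b = ΔG_int + ΔG_tr for a tightly bound ion.
"""

from ionsite import (
    FluctuationStats,
    binding_free_energy,
    delta_delta_g,
    format_binding_table,
    gen_bound_ion_positions,
    sigma_for_entropy,
    translational_entropy,
)

pos = gen_bound_ion_positions((0.3, 0.3, 0.3), 100_000, seed=0)
dg_tr_sampled = translational_entropy(pos)
dg_tr_closed = translational_entropy(FluctuationStats((0.3,) * 3, 1))
print(f"ΔG_tr from 10⁵ samples : {dg_tr_sampled:.4f} kcal/mol "
      f"(closed form {dg_tr_closed:.4f})")
print(f"σ giving ΔG_tr = 4.6   : {sigma_for_entropy(4.6):.4f} Å per axis")

site = binding_free_energy(-23.3, 4.6, 1.2, site_label="tight site")
alt = binding_free_energy(-19.3, 4.6, 0.9, site_label="alternative site")
print()
print(format_binding_table([site, alt]), end="")
ddg = delta_delta_g(site, alt)
print(f"\nΔΔG (tight − alternative) = {ddg.value:+.1f} ± {ddg.error:.1f} kcal/mol")
print("A negative ΔΔG means the tight site binds the ion more favourably.")
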