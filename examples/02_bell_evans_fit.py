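"""Maximum-likelihood Bell-Evans fit of a loading-rate dependence cloud.

Draws rupture events at the nine study pulling velocities from known
kinetics (koff = 0.01 /s, x_beta = 0.3 nm) and recovers the parameters.
"""

from vwforce import STUDY_VELOCITIES, bell_evans_lifetime, fit_bell_evans, gen_rupture_dataset

events = gen_rupture_dataset(
    koff=0.01, x_beta=0.3,
    velocities=STUDY_VELOCITIES,  # 50 ... 3000 nm/s
    keff_mean=10.0, keff_sd=2.0,  # per-cycle effective spring, pN/nm
    n_per_velocity=1000, seed=2,
)
fit = fit_bell_evans(events)
print(f"koff  = {fit.koff:.4f} +/- {fit.se_koff:.4f} 1/s   (truth 0.01)")
print(f"x_beta = {fit.x_beta:.3f} +/- {fit.se_x_beta:.3f} nm  (truth 0.3)")

# The fitted parameters feed the Bell lifetime law tau(F) = tau0 e^{-x F/kT}:
for F in (0.0, 5.0, 20.0):
    tau = bell_evans_lifetime(F, fit.tau0, fit.x_beta)
    print(f"lifetime at {F:5.1f} pN: {tau:10.2f} s")
# Lifetimes fall exponentially with tension - the basis of VWF force sensing.
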