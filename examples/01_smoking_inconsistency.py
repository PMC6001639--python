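"""Fit the smoking-cessation benchmark and quantify network inconsistency.

Fits the consistency model and the design-by-treatment interaction (Jackson)
model to the classic 24-trial smoking-cessation network and prints the
heterogeneity (tau) and inconsistency (kappa) standard deviations, the DIC of
each model, and the relative effect of individual counselling versus no
contact.  A kappa posterior concentrated away from zero, or a DIC drop, would
flag disagreement between trial designs; here both models fit about equally
well, so the network shows no strong inconsistency.
"""

import nmala as nm

net = nm.load_smoking()
cat = nm.enumerate_designs(net)
print(f"{net.n_studies} trials, {net.n_treatments} treatments, "
      f"{cat.n_designs} designs, {len(cat.omega_slots)} inconsistency effects\n")

for kind in ("consistency", "jackson"):
    res = nm.fit(nm.ModelSpec(kind, "binomial"), net)
    tau = res.marginals["tau"]
    line = (f"{kind:>12}:  tau {tau.median():.2f} "
            f"[{tau.quantile(0.025):.2f}, {tau.quantile(0.975):.2f}]")
    if kind == "jackson":
        kap = res.marginals["kappa"]
        line += (f"   kappa {kap.median():.2f} "
                 f"[{kap.quantile(0.025):.2f}, {kap.quantile(0.975):.2f}]")
    print(line + f"   DIC {res.dic.dic:.2f} (pD {res.dic.pd:.1f})")

d13 = res.marginals["d[1,3]"]
print(f"\nindividual counselling vs no contact (Jackson model): "
      f"log-odds ratio {d13.median():.2f} "
      f"[{d13.quantile(0.025):.2f}, {d13.quantile(0.975):.2f}]")
print("tau ~ 0.8 signals substantial between-trial heterogeneity; "
      "kappa's wide interval around 0.4 means inconsistency is uncertain "
      "but not clearly present (the DICs are nearly equal).")
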