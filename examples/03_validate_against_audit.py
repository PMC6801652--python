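"""Validate coder output against a (simulated) street audit.

The audit is the gold standard: the comparison yields per-cell count
pairs, false-positive/false-negative rates from one-to-one facility
matching, and the agreement statistics (paired t, Bland-Altman,
ICC(A,2), Krippendorff's alpha).
"""

import flcoder as flc

city = flc.generate_city(flc.CitySpec(seed=1))
grid = city.grid()
coded = flc.code_facilities(city.places)

# audit with realistic error structure: 14% coder phantoms, 8% misses
noise = flc.AuditNoiseSpec(seed=2, fp_rate=0.14, fn_rate=0.08, gps_sd_m=5.0)
audit = flc.simulate_audit(city, noise, grid)

sampled = flc.draw_sample(grid, flc.sample_size_finite(len(grid)).n, seed=7)
audit = [a for a in audit if a.grid_id in set(sampled)]

out = flc.validate_against_audit(coded.facilities, audit, grid, sampled, city.zone)
rep = out.report

fp, fn = flc.fp_fn_rates(out.confusion_overall)
print(f"sampled cells: {len(sampled)}")
print(f"estimated FP rate {fp:.1%} (injected 14%), FN rate {fn:.1%} (injected 8%)")
print(f"exact agreement {rep.agreement_tol0:.1%}; within +-1 facility {rep.agreement_tol1:.1%}")
t = rep.paired
print(f"paired t = {t.t:.3f} (df {t.df}, p = {t.p_value:.3f}): "
      "no systematic difference" if t.p_value > 0.05 else "systematic difference")
for s in rep.strata:
    print(f"  {s.stratum:>20}: ICC = {s.icc.icc:.3f} "
          f"[{s.icc.ci_low:.3f}, {s.icc.ci_high:.3f}] ({s.icc.band}), "
          f"alpha = {s.alpha.alpha:.3f}")
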