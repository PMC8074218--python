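"""Build the two-factor central composite design behind the bundled study.

The factors are the core:shell mass ratio (core varies, shell fixed at 5)
and the maltodextrin:gum-arabic ratio (maltodextrin varies, MD + GA = 5).
A rotatable CCD with five center replicates gives 4 factorial + 4 axial +
5 center = 13 runs with axial points at coded distance 2^(2/4) = 1.414.
"""

import microenc as me

spec = me.quebracho_design_spec()
table = me.generate_ccd(spec)
print(table.frame.to_string(index=False))
print(f"\nruns: {table.n_runs}, axial distance: {spec.alpha_value:.3f}")

report = me.validate_design(table, spec)
print(f"design valid: {report.ok}")
print(f"coded cross product x1*x2: {report.orthogonality['core_shell*md_ga']}")
# The coded columns are balanced and mutually orthogonal, which is what
# makes the quadratic coefficient estimates independent of one another.
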