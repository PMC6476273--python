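"""Positive transcriptional feedback on receptor and Galpha expression.

Compares the pathway with and without feedback production of Ste2/Gpa1
(receptor feedback one order of magnitude above Galpha feedback). Feedback
raises the saturating-ligand output and roughly doubles total receptor at
steady state while leaving basal signaling almost untouched — amplification
without leak.
"""

from gpcrtune import default_feedback_rates, simulate_feedback

rates = default_feedback_rates()  # calibrated default feedback strength
L_SAT = rates.L_tot  # 100 uM, saturating

for label, L in (("basal (L = 0)", 0.0), (f"saturating (L = {L_SAT:g} M)", L_SAT)):
    on = simulate_feedback(rates, L, t_end=1000.0, with_feedback=True)
    off = simulate_feedback(rates, L, t_end=1000.0, with_feedback=False)
    print(f"{label}:")
    print(f"  free Gbetagamma readout  with feedback {on.readout:.3e} M, "
          f"without {off.readout:.3e} M  (ratio {on.readout/off.readout:.2f})")
    print(f"  total receptor           with feedback {on.receptor_mass:.3e} M, "
          f"without {off.receptor_mass:.3e} M")

print(
    "\nFeedback boosts the stimulated output and receptor pool while the"
    "\nbasal readout stays within a factor ~1 of the no-feedback system."
)
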