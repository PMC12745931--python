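"""Close the loop: validate the model against pseudo-observed loggers.

Runs the forward model on a reduced nest, overlays realistic logger noise to
fabricate "observed" series at the base/centre/top logger positions, then
scores the model against them with the eight-hourly RMSE / R2 / MAE / ME
metrics used for field validation.
"""

from nestherm.config import with_overrides
from nestherm.synthetic import make_reference_nest, simulate_observed
from nestherm.validation import metrics_table

config = make_reference_nest(seed=2)
config = with_overrides(
    config,
    geometry={"clutch_size": 12, "nest_depth_m": 0.50},
    scenario={"duration_days": 10.0},
)

observed, run = simulate_observed(config=config, seed=2)
table = metrics_table(
    {loc: observed[loc] for loc in ("base", "centre", "top")},
    run.probes,
)
print("model vs pseudo-observed loggers (eight-hourly stamps):")
print(table.round(3).to_string())
print()
print("The observations are the model's own output plus logger noise, so")
print("RMSE sits at each logger's noise floor (0.2 C at the base logger,")
print("1.0 C at the button loggers).  R2 is noise-limited too: over 10 days")
print("the true signal at clutch depth varies by well under a degree, so the")
print("1.0 C button loggers bury most of it (R2 recovers over a full season,")
print("where the ~3 C warming trend dominates).  With noise set to zero")
print("every metric collapses to its perfect value.")
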