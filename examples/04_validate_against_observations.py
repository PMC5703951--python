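"""Validate new predictions against an external observation table.

Simulates the intended deployment: some causes are hidden from the graph
(as if not yet in public databases), a model is trained on the reduced
graph, and its new predictions are checked against an independently
generated observation table (a stand-in for EHR-derived associations,
sensitivity 0.8, noise 0.05). Significance comes from 100,000 random models
that each predict the same number of drugs uniformly from the eligible
non-cause pool.
"""

from adrkg import (
    NoModel,
    PlantedSpec,
    generate_graph,
    generate_observations,
    hold_out_causes,
    random_model_significance,
    select_predictors,
    train_model,
)

g, truth = generate_graph(PlantedSpec(seed=7))
g2, held = hold_out_causes(g, truth, fraction=0.3, seed=1)
print(f"hidden causes: {sorted(d.identifier for d in held)}")

ps = select_predictors(g2, truth.target_adr)
assert not isinstance(ps, NoModel)
model = train_model(g2, ps)

obs = generate_observations(g2, truth, sensitivity=0.8, noise_rate=0.05, seed=2)
report = random_model_significance(model, g2, obs, n_iter=100_000, seed=3)

print(f"N (tested new predictions)  {report.n_predictions}")
print(f"V (validated in obs table)  {report.n_validated}")
print(f"E (expected under null)     {report.expected_validated:.3f}")
print(f"p (random >= trained)       {report.p_random:.4f}")
print(f"significant at 5%:          {report.significant}")
# A significant result means far fewer than 5% of random models matched the
# trained model's validation count — the predictions carry real signal.
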