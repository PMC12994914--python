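# Full demonstration run: 3 lighting scenarios × 2 sleep types × 3 view
# depths over a calendar year.  Expect ~40 min of wall time on one CPU
# (36 annual integrations); shrink year_days for a quick look.
schema: 1
year_days: 365
start_date: 2021-01-01
dt_model_s: 20
scenarios: [daylight, electric, dimming]
sleep_types: [scheduled, disrupted]
view_depths: [0.0, 0.5, 1.0]
plots: true
out_dir: insom_results
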