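# File formats

All tables are plain CSV with a header row; times are seconds from
session start, written with full round-trip precision (decimal point,
no locale). All intervals are half-open `[start, end)`.

## Inputs / stage outputs

| file | columns | notes |
|---|---|---|
| `spikes.csv` | `unit_id, time_s` | timestamps sorted within each unit, `0 <= t < session_dur` |
| `timeline.csv` | `label, time_s` | `label ∈ {CS_ON, CS_OFF, US_ON, US_OFF}`, sorted by time |
| `protocol.yaml` | SessionProtocol fields + `total_dur` | sidecar for `timeline.csv` |
| `bouts.csv` | `start_s, end_s` | freezing bouts, sorted, pairwise disjoint |
| `freeze_events.csv` | `type, time_s` | `type ∈ {onset, cessation}`, sorted by time |
| `truth.csv` | `unit_id, label, multiplier` | simulator ground truth (`label` is `;`-joined) |

## Analysis outputs

| file | columns | notes |
|---|---|---|
| `freezing_summary.csv` | `epoch, n_obs, percent_freezing` | `percent_freezing` blank when the epoch has zero observations |
| `classification.csv` | `unit_id, label, responsive, direction, supra_bins` | one row per unit × alignment; skipped alignments have blank `responsive` and the reason in `direction` |
| `zprofiles.csv` | `unit_id, label, bin_left_s, z` | trial-averaged z per bin |
| `unit_rates.csv` | `unit_id, mean_rate_hz` | session-wide mean firing rate |
| `group_summary.csv` | `group, label, n_responsive, n_total, percent` | |
| `comparisons.csv` | `label, group_a, group_b, a, b, c, d, p_two_sided` | `a,b` = group A responsive/non-responsive; `c,d` = group B |
| `paired_t.csv` | `label, n, t, df, p, degenerate` | baseline-vs-post mean z across responsive units |
| `manifest.json` | config hash, seed, version, per-stage files, exclusion logs | sufficient to re-run bit-identically |

## Configuration

Pipeline config is YAML with sections `protocol` (`kind`), `classifier`
(ClassifierParams fields), `simulation` (`groups`, `behavior`),
`sampling` (`sample_interval`), plus top-level `seed` and `output_dir`.
Unknown keys anywhere are rejected. See `examples/demo_config.yaml`.

Malformed rows (missing columns, negative or unsorted times) raise an
error naming the offending line number.
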