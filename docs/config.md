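# Pipeline configuration (`photokv run --config cfg.yaml`)

The config is a YAML mapping. All keys are optional; defaults reproduce the
demo conditions. See `examples/demo_config.yaml` for a complete example.

```yaml
seed: 1                      # base seed; stages derive their own from it
stages: [tension, cm, profiles, single_channel, iv]
```

## `tension` — torus-relaxation model

| key | unit | default |
|---|---|---|
| `r0_um` | µm | 29.5 |
| `rin_um` | µm | 27.5 |
| `sigma0_mN_per_m` | mN/m | 4.0 |
| `eta_h_nNs_per_m` | nN·s/m | 500.0 |
| `tau_ms` | ms | 23.0 |

The same block feeds the `profiles` stage's radius trajectory.

## `cm` — capacitance stage

| key | unit | default |
|---|---|---|
| `c_base_pF` | pF | 80.0 |
| `dc_frac` | fraction | −0.06 |
| `tau_relax_ms` | ms | 23.0 |
| `noise_sd_pF` | pF | 0.05 |
| `t_on_ms` | ms | 100.0 |
| `pulse_ms` | ms | 40.0 |
| `duration_ms` | ms | 500.0 |

## `profiles` — torus imaging stage

| key | unit | default |
|---|---|---|
| `frame_ms` | ms | 40.0 |
| `noise_sd` | intensity | 0.02 |
| `n_frames` | count | 8 |
| `switch_frame` | index | 3 (last pre-switch frame) |

## `single_channel` — gating stage

| key | unit | default |
|---|---|---|
| `n_channels` | count | 3 |
| `p_open_cis` / `p_open_trans` | probability | 0.05 / 0.30 |
| `voltage_mV` | mV | 120.0 |
| `noise_sd_pA` | pA | 1.0 |
| `duration_ms` | ms | 3000.0 |

## `iv` — ensemble stage

| key | unit | default |
|---|---|---|
| `v_half_cis_mV` / `v_half_trans_mV` | mV | 158.6 / 120.9 |
| `v_s_mV` | mV | 15.0 |
| `g_max_nS` | nS | 2.0 |
| `noise_sd_pA` | pA | 5.0 |
| `n_replicates` | count | 5 |
| `mode` | `peak` \| `steady` | steady |
| `v_test_mV` | mV | 120.0 |

Outputs land in `--out`: delimited-text traces/tables per stage plus
`manifest.json` recording the config snapshot, its SHA-256 hash, the seed,
per-artifact checksums, stage reports and timings.
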