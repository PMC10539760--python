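1H NMR (500 MHz, DMSO-d6) Shift 10.54 (s, 1H), 7.44 (d, J = 7.7 Hz, 1H), 7.23 (d, J = 8.0 Hz, 1H), 7.03 (td, J = 7.9, 1.2 Hz, 1H), 6.99 (t, J = 8.2 Hz, 1H), 6.97 (td, J = 8.0, 1.2 Hz, 1H), 6.89 (d, J = 7.9 Hz, 1H), 6.28 (br d, J = 8.2 Hz, 1H), 5.14 (s, 1H), 4.51 (dt, J = 47.5, 6.1 Hz, 2H), 4.00 (t, J = 5.6 Hz, 2H), 3.46 (dq, J = 16.0, 10.6 Hz, 1H), 3.37–3.33 (m, 1H), 2.99 (dq, J = 16.0, 10.0 Hz, 1H), 2.90 (t, J = 5.7 Hz, 2H), 2.78 (dd, J = 16.0, 4.5 Hz, 1H), 2.69 (t, J = 6.9 Hz, 2H), 2.62 (dd, J = 16.0, 7.7 Hz, 1H), 2.53–2.51 (m, 1H), 2.28 (s, 3H), 1.85–1.74 (m, 2H), 1.06 (d, J = 6.7 Hz, 3H)
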