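1H NMR (500 MHz, DMSO-d6) Shift 10.18 (s, 0.5H, isomer1), 10.14 (s, 0.5H, isomer2), 7.39 (d, J = 7.6 Hz, 1H, isomer1+isomer2), 7.18 (t, J = 7.2 Hz, 1H, isomer1+isomer2), 7.09 (d, J = 8.5 Hz, 0.5H, isomer2), 6.99–6.95 (m, 1H, isomer1+isomer2), 6.95–6.90 (m, 1H, isomer1+isomer2), 6.88 (d, J = 8.4 Hz, 0.5H, isomer2), 6.84 (s, 1H, isomer1), 5.38 (s, 0.5H, isomer1), 5.29 (s, 0.5H, isomer2), 4.54 (dt, J = 47.5, 6.0 Hz, 1H, isomer1), 4.44 (dt, J = 47.5, 6.0 Hz, 1H, isomer2), 4.07–3.95 (m, 1H, isomer1), 3.95–3.85 (m, 1H, isomer2), 3.67–3.56 (m, 1H, isomer1+isomer2), 3.39 (s, 1H, isomer1+isomer2), 3.14- 3.04 (m, 1H, isomer1+isomer2), 2.94 (br t, J = 5.4 Hz, 1H, isomer1), 2.80 (br t, J = 5.6 Hz, 1H, isomer2), 2.77 (br d, J = 4.5 Hz, 1H, isomer1+isomer2), 2.72 (t, J = 7.0 Hz, 1H, isomer1), 2.69 (br d, J = 15.0 Hz, 1H, isomer1+isomer2), 2.60 (t, J = 6.9 Hz, 1H, isomer1+isomer2), 2.44 (s, 1.5H, isomer2), 2.39 (s, 1.5H, isomer2), 1.83 (br dquin, J = 26.2, 6.6 Hz, 1H, isomer1), 1.82 (s, 1.5H, isomer2), 1.80 (s, 1.5H, isomer1), 1.72 (dquin, J = 26.2, 6.4 Hz, 1H, isomer2), 1.14 (d, J = 6.5 Hz, 3H, isomer1+isomer2)
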