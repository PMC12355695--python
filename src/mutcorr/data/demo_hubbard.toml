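# Demo: half-filled 8-site chain scan at weak and strong coupling.
# Run: mutcorr hubbard --sites 8 --u 1.0 --n-states 100 --out scan_u1.csv
#      mutcorr hubbard --sites 8 --u 8.0 --n-states 100 --out scan_u8.csv
[model]
sites = 8
t = 1.0
u_values = [1.0, 8.0]
n_states = 100
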