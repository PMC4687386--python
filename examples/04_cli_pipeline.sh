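#!/bin/sh
# The same pipeline from the shell: write a toy network, enumerate its
# EFMs, and run the GA with a key=value config file.
set -e
workdir=$(mktemp -d)

gamcs make-toy "$workdir/toy.tsv"
gamcs enumerate "$workdir/toy.tsv" "$workdir/efms.tsv" --roles "$workdir/toy.roles"

cat > "$workdir/ga.cfg" <<EOF
t=50
p=30
r_m=0.4
cross=1point
elit=0.1
new_S=0.1
t_stop=15
min_1s=0.9
w_k=0.03
seed=0
objective=F1
w1=1
w3=1
EOF

gamcs run-ga "$workdir/toy.tsv" "$workdir/out" \
    --config "$workdir/ga.cfg" --roles "$workdir/toy.roles" \
    --efm-matrix "$workdir/efms.tsv"

echo "--- best designs ---"
cat "$workdir/out/result.txt"
echo "results in $workdir/out (result.txt, trajectory.tsv, manifest.json)"
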