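"""Interchange: ms-style text round trips and polarized VCF windows."""

import pathlib
import tempfile

import hafscore as hs

tmp = pathlib.Path(tempfile.mkdtemp())

# --- ms text ------------------------------------------------------------
params = hs.DemographyParams(theta=12, n=10, window_length=50_000)
samples = [s.matrix for s in hs.simulate_neutral(params, 2, seed=3)]
ms_path = tmp / "neutral.ms"
hs.write_ms(samples, ms_path, window_length=50_000)
back = list(hs.read_ms(ms_path, window_length=50_000))
print(f"wrote and re-read {len(back)} ms replicates; "
      f"first has {back[0].num_sites} segregating sites")

# --- VCF with ancestral-allele polarization ------------------------------
vcf_text = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t1000\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|0
1\t2000\t.\tC\tT\t.\tPASS\tAA=T\tGT\t0|1\t0|0
1\t3000\t.\tG\tA\t.\tPASS\t.\tGT\t0|1\t0|0
"""
vcf_path = tmp / "toy.vcf"
vcf_path.write_text(vcf_text)

window = hs.WindowSpec.from_center("1", center=2000, width=4000)
matrix = hs.read_vcf_window(vcf_path, window)
print(f"VCF window {window.start}-{window.end}: {matrix.n} haplotypes x "
      f"{matrix.num_sites} polarized sites (site 3000 dropped: no ancestral call)")
print("derived counts:", matrix.derived_counts())
# At site 2000 the ALT allele is ancestral, so REF carriers are scored as
# derived: polarization flips the genotype bits.
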