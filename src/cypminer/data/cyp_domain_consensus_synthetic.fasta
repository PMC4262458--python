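>cyp_domain_consensus_synthetic length=463 motifs=ihelix@300,khelix@355,perf@405,heme@425
MECLLGSLNQWIFPLLQLAPILIPLPWTMVDDCGEDRQDGARSPKTPSAAPAFFVWGIFI
VKDNFVIKEADPMFESKLPSFGPARQVSDEVGGASPIQTCHQRYTISYPAIEPIADCSIA
GVAELLNRSSLINAQLNVGNWQILQASASLMVPQLWTKRMAGVAYKHVLSLKFLSVVPAL
SSELHITPEYKNPRLAIHGELMRVDDDYLATSMVYPGESKIDSMSPQMGEQISPEGACPM
HPAKDPGGTSAAKIPEIGQRRTITKFPVQKDGVLSSGAVESNVRALLSCVEKVKEGNSYS
AGTDTYFQGSLSLNYYRICPYFLVVAHDEYGDTESILALKDTAMALLSNVIAERWETLRV
GLSTNMIHHRQTNALNFIKYAKANILLRLHARVVNRKGLEKEYAHFIPERFEAKLMLGES
LTEFYPFGAGRRSCIGYFRRLTRIATWPVMQDAKAVWTKIGIR
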