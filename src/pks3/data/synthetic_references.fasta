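>PpASCL_syn synthetic reference scaffold
SPTFVVSSRVGYNSECLGIKPRALSDISNFPVEGIDNICFHIFESSSELNNSSLMGVLER
MIPSKLLHAHDGCCAQEMLSMGSNARPINLNFIGEKGRRVYFKVSPIERFIEDLDIPPRK
LMRGAIKYQKNYLGRAVIGHVIVVIQELHASWNMRFQMPSRYCALGTAECELQVKAMVWP
WWLESMGRPRVCRTADKTSESVMDVCKFRLFLPWPPDLFREIVVGYLLKESHAKHNISGA
TSCLKTAGGRMTIQCPSRAKNSENYDEVRAADVKFGLLGTADRQLLASLRSTYRTYVSSK
PNLLHIGKQNVGCGGEGFEVYIDTNHPLKEPNFTNKRNRVAISASSVQKHKDLLILSTIK
YRRRTRGIDGFGPGAKVGGPLVSITVPVQTKRKLAIAEII
>PpORS_syn synthetic reference scaffold
SHTFRISGRVADTSIHLASKDGTWSRIAKFPVEGIDDVCFRTFENSGEFTDASSFSLLNR
MLLSNMLEAHDAVCDHEMLSMGTNARPINLNYIEEKGRRVYFRVTPIQRYLEEVSTEPHK
LMRGAIEKRKNYLGKAVISRITILIQELHASWNLKFQMPSRYCASGTGECEHQVNAHVWP
WWLEETGRPQVCQFSDKAYEAVLNACSFRLFLDTPPNQHGELVVLYTLKRNHVKYSISAL
NSCLRTKGGHMEIQCPSRAKSSENYTENRASDAKFGVLTTAEPEVAGGLRSAYRTYLSSE
ANLLHLGKVNIGCISDGFEVYIELTMSLKYVDFTTKRNRVNVSKSSVQKKQELLILAAIK
QRGRLHSFEGFGPGNDVHGPLINIGVPVRTKRKYSIKEIL
>PKSIII_generic_syn synthetic reference scaffold
SHTFRASSRIGYKSICLASRAGVWGEIASLPVEGIDNICFHTFDTPGEFSDANMFSLLNV
IILTKLLSAHSGTCAQELLSMGSNTKPINLNFIGEKERRVYFQFSPIQRYIGEANTPAHK
LMAGAVENREQYLSMSIISRIFVLVQELHASWNLKIQMPGRYCALGPCECDPQVTAHVWP
WGLVTHGRPRVCRAIDKTDESQYNACTFKLFVETPPNLYSEIMVLYALKRSHAEYTISTL
SACLKTKGGHMTWKCLFRTKCSENYNENRATDAKFGLVTTANCQLLVGMRAPYQTYVSSK
STLLHIGKQDIGCGGEGYQLYIELTLSLEEPDFTNKQNGVHMSGSSMQKRQDLLILTSIK
VRKKMHNGEGFGPGNNVHVPMVSIGVPVRIKRKFPIHEFI
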