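>ScV-LA-RdRp-standin synthetic stand-in RdRp reference; motif blocks I-VIII, GDD at 601
HGNHCMRPITNTNFNYCLSHYSHFMGFIKFIGTRQLLPRNFVYCIEEAQMWMTDDVWYTR
FFVWESWMPLRPEDWTGECDTSPADGVFMEELKYSVKHKWNRNDEIPLTESGCLIVFGQD
YCSQNKVMGPYFDDDRLRKCGPLFWPAQMSKEECIIETRWLRCQTPIAFNHEKPLPDDKR
WGVTCKQYKQVWFWWQNYESCETYPTLVKKTDGHPWNTAELIERWWFIPRSPLHCDASML
FKHMWQWHSYTCRFLEWPFNICNGRGHIYMYGILWVERLLAKWFIFPVDVWNSTWTLTHV
TCVSPFPPSQTQPQCVNFLKVRYHMWCLMSKWPHQANYDNQETPRQDAHGLFTKDICHAE
GPAWFTMHCEPHGLGDMTIVWTVGQQHECLTHRWEKYPEKTGNPNTMWFVPGKSAEYDAY
EHQSKHIPEDCYECQSGKWGQPMSLTFEWQMVFFSITVPVQGYFACADHPTFGHENCVLS
EHLIYAEYNNWYQSTDRPFKDQRWAWVKWHDNTTGGRHTDFSKFDQFKMERRYKLFKQTW
IEDNAKIQWIRCSQIDPAYSGQRATSKMNFYPAIMDGVYLTQPHSLMPEKGFSQQHTRWY
GDDSLIIIPISPHFPWLWAYHEYQTADATCDESPELRLNNTLLNAVWLYMRWCWCKGKQS
ASMAWTQGSHENNYPEDTLEFLRRHFEHPRMRMDEKTTNHRTTIRLLGIRLSNWYLITRK
WKRDAVQHEQHQYKVQARNIASHASPYCEMITCWWQYTHHWCAGLSWSRPEAGVNQIKEL
CGVFRWHAVIAYRFTPKAMVVQPWHIHWGTTHFSETGFMFWSSFPTGHKPIYWGEKYGIH
SEWSRFITFPVLCCSWEQKDYSEHQPHD
>ScV-LBC-RdRp-standin synthetic stand-in RdRp reference; motif blocks I-VIII, GDD at 601
YVWLLGELAYTTALSIVVPARLNTHMDFIMNMMSKHDYVVQSTDVVRIWIHCKYNAELGS
RWYGSRWTHNLTRRSWWMPLQGAFQAQWQFWRIVWLSMIQLWMGWETCGMLVSNASATID
QAKRFWWSCHASGCEPTDSMVEHDINSNYQGLSKWEPPHACRHSIKFVTGHNDCIENYWE
HMMMVDGHKCETCRAPYTYISTRNHYQRPGVDDDACSIHDMETLAHTALHLRYCSIWPPP
NQKQLYPFRHHYCHQPPMFNHTFLRPPSIMTVKNNWCLFPSTFQHPSQRNVEDKINIWVR
VPVYSHQNKVRFLDGHGYYQDQANNKNIYPLITDIYFWILGHAPALFGIWMTQHDCDNVW
DHVIWGAVRDLERTNAPLMSHYQGYPTDGVNMFAALCQPKTGNPNTRRFQLVRRGHYRSV
MDGSVGYKIQPGLEASITKGQPMSLTYQFARNFQYLAIKPGCCTMNIKEERTQHSFPKCS
EHLIYAYYAVSCKMDRCFDWKNQQGPPIMEDWKGNTNRQDFSKFDQQQNPECWAHMFIVG
HDCQQTHEMRHAGNSMQGQSGQRATSPACELWSKKVIMKSCMIKGYDALIECYCMYDPSY
GDDSLISVWNGASRKPGDITQDRYDLTVPASVSHQNAEWNTLLNAVNKQQHMVPFIVDEH
DWAIIVHRWLMVSCGGKTMEFLRRHFLLHEIQNNRRCCHMYDRNIKERHAWIEGMEPNEW
GSFDNCVNVEFCHWGVDNQTFAKTAMPNFFALNGPKCSGCYAFQCTAWCEICHNMQQWMK
HRWTTMQIFCWVKACNEPVYHCMTNGTLLYEYWGCSEHQQQFCPFAQMQTKKEYMETTWM
WHDALDCKQVMCQCICVIFYIT
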