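<?xml version="1.0" encoding="UTF-8"?>
<mediawiki xmlns="http://www.mediawiki.org/xml/export-0.10/" version="0.10">
  <page>
    <title>Toracece_bemibuti</title>
    <ns>0</ns>
    <id>1</id>
    <revision>
      <id>103</id>
      <timestamp>2011-01-01T01:38:00Z</timestamp>
      <contributor>
        <username>Poda</username>
      </contributor>
      <comment>edit 1</comment>
      <text>Content of Toracece_bemibuti, revision 103.</text>
    </revision>
    <revision>
      <id>108</id>
      <timestamp>2011-01-01T05:11:00Z</timestamp>
      <contributor>
        <username>Nedo</username>
      </contributor>
      <comment>edit 2</comment>
      <text>Content of Toracece_bemibuti, revision 108.</text>
    </revision>
    <revision>
      <id>111</id>
      <timestamp>2011-01-01T05:30:00Z</timestamp>
      <contributor>
        <username>Nebusi</username>
      </contributor>
      <comment>edit 3</comment>
      <text>Content of Toracece_bemibuti, revision 111.</text>
    </revision>
    <revision>
      <id>112</id>
      <timestamp>2011-01-01T07:02:00Z</timestamp>
      <contributor>
        <username>GofobuBot</username>
      </contributor>
      <comment>edit 4</comment>
      <text>Content of Toracece_bemibuti, revision 112.</text>
    </revision>
    <revision>
      <id>119</id>
      <timestamp>2011-01-01T11:10:00Z</timestamp>
      <contributor>
        <username>Bolo</username>
      </contributor>
      <comment>edit 5</comment>
      <text>Content of Toracece_bemibuti, revision 119.</text>
    </revision>
  </page>
  <page>
    <title>Gevanemo_tasebepu</title>
    <ns>0</ns>
    <id>2</id>
    <revision>
      <id>105</id>
      <timestamp>2011-01-01T03:07:00Z</timestamp>
      <contributor>
        <username>Bolo</username>
      </contributor>
      <comment>edit 1</comment>
      <text>Content of Gevanemo_tasebepu, revision 105.</text>
    </revision>
    <revision>
      <id>106</id>
      <timestamp>2011-01-01T04:20:00Z</timestamp>
      <contributor>
        <username>Poda</username>
      </contributor>
      <comment>edit 2</comment>
      <text>Content of Gevanemo_tasebepu, revision 106.</text>
    </revision>
    <revision>
      <id>114</id>
      <timestamp>2011-01-01T07:29:00Z</timestamp>
      <contributor>
        <username>GofobuBot</username>
      </contributor>
      <comment>edit 3</comment>
      <text>Content of Gevanemo_tasebepu, revision 114.</text>
    </revision>
    <revision>
      <id>116</id>
      <timestamp>2011-01-01T07:38:00Z</timestamp>
      <contributor>
        <username>GofobuBot</username>
      </contributor>
      <comment>edit 4</comment>
      <text>Content of Gevanemo_tasebepu, revision 116.</text>
    </revision>
    <revision>
      <id>117</id>
      <timestamp>2011-01-01T09:29:00Z</timestamp>
      <contributor>
        <username>Nebusi</username>
      </contributor>
      <comment>edit 5</comment>
      <text>Content of Gevanemo_tasebepu, revision 117.</text>
    </revision>
  </page>
</mediawiki>
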